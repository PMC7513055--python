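"""End-to-end orchestration: simulate -> extract -> select -> classify.

Feature sets are named column groups over one full feature matrix:

* ``LF``      — the 186 linear features
* ``LFHFD``   — LF plus the 27 Higuchi fractal-dimension features (213)
* ``LFCFD``   — LF plus the 27 Castiglioni FD features (213)
* ``LFE``     — LF plus the 12 Shannon-entropy features (198)
* ``LFHFDE``  — LF + Higuchi FD + entropy (225)
* ``LFCFDE``  — LF + Castiglioni FD + entropy (225)

An ``S`` prefix (SLF, SLFCFD, ...) denotes the ANOVA-selected subset of
the same group: its columns intersected with the features kept at the
configured significance level.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from .classify import ClassifierConfig, default_classifier_grid, run_experiment_grid
from .errors import ValidationError
from .linear_features import (
    CatalogSpec,
    FeatureMatrix,
    default_linear_catalog,
    extract_linear,
    _channel_sets,
)
from .nonlinear_features import NonlinearConfig, extract_nonlinear
from .selection import anova_select, apply_selection
from .synthetic import CohortSpec, generate_cohort
from .tablet_io import Recording, read_svc

logger = logging.getLogger(__name__)

BASE_SET_NAMES = ("LF", "LFHFD", "LFCFD", "LFE", "LFHFDE", "LFCFDE")
SET_NAMES = BASE_SET_NAMES + tuple("S" + s for s in BASE_SET_NAMES)

_SET_PREFIXES = {
    "LF": (),
    "LFHFD": ("hfd.",),
    "LFCFD": ("cfd.",),
    "LFE": ("ent.",),
    "LFHFDE": ("hfd.", "ent."),
    "LFCFDE": ("cfd.", "ent."),
}


def extract_features(
    recordings: list[Recording],
    catalog: CatalogSpec | None = None,
    nl_config: NonlinearConfig | None = None,
) -> FeatureMatrix:
    """Build the full (linear + non-linear) feature matrix for a cohort."""
    if not recordings:
        raise ValidationError("no recordings to extract features from")
    catalog = catalog or default_linear_catalog()
    nl_config = nl_config or NonlinearConfig()
    rows, labels, meta = [], [], []
    for rec in recordings:
        sets = _channel_sets(rec)  # shared between both extractors
        lin = extract_linear(rec, catalog, channel_sets=sets)
        nl = extract_nonlinear(rec, nl_config, channel_sets=sets)
        rows.append({**lin.values, **nl.values})
        labels.append(rec.label)
        meta.append({"subject_id": rec.subject_id, "hand": rec.hand})
    X = pd.DataFrame(rows)
    return FeatureMatrix(X=X, labels=pd.Series(labels), meta=pd.DataFrame(meta))


def resolve_feature_sets(
    set_names: list[str],
    all_columns: list[str],
    kept: list[str] | None = None,
) -> dict[str, list[str]]:
    """Map Table-1 style set names to concrete column lists.

    Linear columns are those without a non-linear prefix; ``S`` variants
    intersect their parent with the ANOVA-kept features (order preserved).
    """
    nl_prefixes = ("hfd.", "cfd.", "ent.")
    linear = [c for c in all_columns if not c.startswith(nl_prefixes)]
    out: dict[str, list[str]] = {}
    kept_set = set(kept) if kept is not None else None
    for name in set_names:
        base = name[1:] if name.startswith("S") else name
        if base not in _SET_PREFIXES:
            raise ValidationError(
                f"unknown feature-set name {name!r}; expected one of {SET_NAMES}"
            )
        cols = linear + [
            c for c in all_columns if c.startswith(_SET_PREFIXES[base])
        ]
        if name.startswith("S"):
            if kept_set is None:
                raise ValidationError(
                    f"set {name!r} requires an ANOVA selection result"
                )
            cols = [c for c in cols if c in kept_set]
        out[name] = cols
    return out


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    input_dir: str | None = None  # directory of SVC files + manifest.csv
    cohort: CohortSpec | None = None  # simulate when no input_dir
    sets: tuple[str, ...] = ("LF", "SLF", "SLFCFD")
    alpha: float = 0.05
    per_fold_selection: bool = False  # leakage-free mode, off by default
    folds: int = 10
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        bad = [s for s in self.sets if s not in SET_NAMES]
        if bad:
            raise ValidationError(f"unknown feature-set names: {bad}")

    def config_hash(self) -> str:
        def default(o):
            return asdict(o) if hasattr(o, "__dataclass_fields__") else str(o)

        blob = json.dumps(asdict(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def load_recordings(input_dir: str | Path) -> list[Recording]:
    """Read every ``*.svc`` file in a directory, taking subject ids and
    labels from ``manifest.csv`` when present."""
    input_dir = Path(input_dir)
    if not input_dir.is_dir():
        raise ValidationError(f"input directory not found: {input_dir}")
    labels: dict[str, str] = {}
    manifest = input_dir / "manifest.csv"
    if manifest.exists():
        mdf = pd.read_csv(manifest)
        labels = dict(zip(mdf["subject_id"].astype(str), mdf["label"].astype(str)))
    recs = []
    for path in sorted(input_dir.glob("*.svc")):
        sid = path.stem
        recs.append(read_svc(path, subject_id=sid, label=labels.get(sid, "unlabeled")))
    if not recs:
        raise ValidationError(f"no .svc files in {input_dir}")
    return recs


@dataclass
class PipelineResult:
    matrix: FeatureMatrix
    selection: "pd.DataFrame"
    results_table: pd.DataFrame
    reports: dict
    manifest: pd.DataFrame | None = None
    out_dir: Path | None = None


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run simulate/load -> extract -> select -> classify and write CSVs."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    manifest = None
    if config.input_dir is not None:
        recordings = load_recordings(config.input_dir)
    else:
        cohort = config.cohort or CohortSpec(seed=config.seed)
        recordings, manifest = generate_cohort(cohort)

    matrix = extract_features(recordings)
    matrix.to_csv(out_dir / "features.csv")

    sel = anova_select(matrix, alpha=config.alpha)
    sel.to_csv(out_dir / "selection.csv")

    feature_sets = resolve_feature_sets(
        list(config.sets), matrix.feature_names, kept=sel.kept_features
    )
    configs = default_classifier_grid(seed=config.seed)
    if config.per_fold_selection:
        # leakage-free mode: S-sets are re-selected inside each training fold
        # of their parent set instead of once on the full cohort
        from .classify import evaluate
        from .selection import one_way_f
        import numpy as np

        parents = resolve_feature_sets(
            [s[1:] for s in config.sets if s.startswith("S")], matrix.feature_names
        )

        def make_selector(alpha):
            def fold_selector(X_train, y_train):
                _, p = one_way_f(X_train, y_train)
                return np.flatnonzero(p < alpha)

            return fold_selector

        rows, reports = [], {}
        for set_name in config.sets:
            if set_name.startswith("S"):
                sub = matrix.subset(parents[set_name[1:]])
                selector = make_selector(config.alpha)
            else:
                sub = matrix.subset(feature_sets[set_name])
                selector = None
            for clf_name, cfg in configs.items():
                rep = evaluate(
                    sub, config=cfg, folds=config.folds, seed=config.seed,
                    fold_selector=selector,
                )
                rep.feature_set = set_name
                rep.classifier = clf_name
                reports[(set_name, clf_name)] = rep
                rows.append(rep.to_row())
        table = pd.DataFrame(rows)
    else:
        table, reports = run_experiment_grid(
            matrix, feature_sets, configs, folds=config.folds, seed=config.seed
        )
    table.to_csv(out_dir / "results_table.csv", index=False)

    log = {
        "seed": config.seed,
        "alpha": config.alpha,
        "sets": list(config.sets),
        "n_recordings": len(recordings),
        "n_features": len(matrix.feature_names),
        "n_kept": sel.n_kept,
        "config_hash": config.config_hash(),
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2), encoding="utf-8")
    if manifest is not None:
        manifest.to_csv(out_dir / "manifest.csv", index=False)
    return PipelineResult(
        matrix=matrix, selection=sel.table, results_table=table,
        reports=reports, manifest=manifest, out_dir=out_dir,
    )


def amplitude_sweep(
    amplitudes: list[float],
    seeds: list[int],
    base_spec: CohortSpec | None = None,
    classifier: ClassifierConfig | None = None,
    folds: int = 10,
    linear_only: bool = True,
) -> pd.DataFrame:
    """Cross-validated accuracy as a function of ET tremor amplitude.

    For each (amplitude, cohort seed) a cohort is generated with the ET
    amplitude overridden, linear features extracted and one classifier
    evaluated.  Returns a tidy frame (amplitude, seed, accuracy); the
    per-amplitude mean across seeds is the monotonicity curve.
    """
    from dataclasses import replace as dc_replace

    base_spec = base_spec or CohortSpec()
    classifier = classifier or ClassifierConfig(kind="knn")
    catalog = default_linear_catalog()
    nl_config = NonlinearConfig(estimators=()) if linear_only else NonlinearConfig()
    rows = []
    for seed in seeds:
        for amp in amplitudes:
            spec = dc_replace(
                base_spec,
                seed=seed,
                et_params=dc_replace(base_spec.et_params, amplitude=amp),
            )
            recordings, _ = generate_cohort(spec)
            matrix = extract_features(recordings, catalog=catalog, nl_config=nl_config)
            from .classify import evaluate

            rep = evaluate(matrix, config=classifier, folds=folds, seed=seed)
            rows.append({"amplitude": amp, "seed": seed, "accuracy": rep.overall_acc})
    return pd.DataFrame(rows)
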