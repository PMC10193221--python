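"""Prediction-robustness experiment: how cross-validated random-forest RMSE
for the cardiac competence index degrades as the source series degrade.

For each perturbation family the pipeline evaluates the unperturbed
condition plus its 75-level grid (optionally thinned).  CCI targets are
computed once from unperturbed data and held fixed; features are re-extracted
from the perturbed series of every condition.  Feature preselection — drop
features constant across the whole condition stack, keep those whose Pearson
correlation with CCI on the unperturbed matrix has two-sided P ≤ 0.10 — is
run once and the selected set frozen for every condition.  Each condition's
score is the mean and standard error over repeated 3-fold cross-validated
RMSEs of a default-parameter random forest; the reference line is the RMSE
of the mean predictor (population SD of the targets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from . import perturb as _perturb
from .cci import compute_cci
from .features import CATALOG_VERSION, extract_all
from .preprocess import PreprocessedRecord, preprocess_record
from .synthdata import CohortConfig, generate_cohort

__all__ = [
    "ConditionResult",
    "ExperimentConfig",
    "condition_plan",
    "preselect_features",
    "cv_rmse",
    "baseline_rmse",
    "run_experiment",
    "find_breakdown_level",
]


@dataclass(frozen=True)
class ConditionResult:
    """Mean/SE of repeated CV RMSEs for one perturbation condition."""

    kind: str
    level: float
    mean_rmse: float
    se_rmse: float
    n_reps: int


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one full experiment run."""

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    folds: int = 3
    reps: int = 25
    alpha: float = 0.10
    families: tuple[str, ...] = _perturb.KINDS
    grid_stride: int = 1
    trim_minutes: float = 5.0
    rf_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("need at least 2 CV folds")
        if self.reps < 1:
            raise ValueError("need at least 1 repetition")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("preselection alpha must be in (0, 1)")


def condition_plan(
    kind: str, stride: int = 1, seed: int = 0
) -> list[_perturb.PerturbationSpec | None]:
    """Ordered conditions one family evaluates: unperturbed (None) + grid.

    ``stride`` thins the 75-level grid by keeping every ``stride``-th spec
    counted from the top, so the highest level is always retained.
    """
    grid = _perturb.build_grid(kind, seed=seed)
    specs = list(grid.specs[stride - 1 :: stride])
    return [None, *specs]


def preselect_features(
    unperturbed: pd.DataFrame,
    cci: np.ndarray,
    all_matrices: list[pd.DataFrame],
    alpha: float = 0.10,
) -> list[str]:
    """Freeze the informative feature set.

    Features whose values never change across the full condition stack are
    dropped as uninformative; of the rest, those whose Pearson correlation
    with CCI on the unperturbed matrix has a two-sided P ≤ ``alpha`` are
    kept, ordered by ascending P.  Raises if nothing survives, listing the
    best P-values for diagnosis.
    """
    if len(unperturbed) < 3:
        raise ValueError("need at least 3 participants for correlation preselection")
    stack = pd.concat(all_matrices, axis=0) if all_matrices else unperturbed
    varying = [c for c in unperturbed.columns if stack[c].nunique() > 1]

    pvals: dict[str, float] = {}
    y = np.asarray(cci, dtype=float)
    for name in varying:
        x = unperturbed[name].to_numpy(dtype=float)
        if np.std(x) == 0.0:
            continue
        r, p = stats.pearsonr(x, y)
        pvals[name] = p
    selected = sorted((n for n, p in pvals.items() if p <= alpha), key=lambda n: pvals[n])
    if not selected:
        best = sorted(pvals.items(), key=lambda kv: kv[1])[:5]
        raise ValueError(f"no feature passed P<={alpha}; best candidates: {best}")
    return selected


def baseline_rmse(targets: np.ndarray) -> float:
    """RMSE of the mean predictor: population SD of the targets."""
    y = np.asarray(targets, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 targets")
    return float(np.sqrt(np.mean((y - y.mean()) ** 2)))


def cv_rmse(
    features: pd.DataFrame | np.ndarray,
    targets: np.ndarray,
    folds: int = 3,
    reps: int = 25,
    seed: int = 0,
    rf_params: dict | None = None,
    kind: str = "",
    level: float = 0.0,
) -> ConditionResult:
    """Repeated k-fold cross-validated random-forest RMSE.

    Each repetition reshuffles the fold partition and the forest seed, fits
    on the training folds, predicts the held-out fold, pools all held-out
    predictions and scores one RMSE; the mean and standard error over the
    repetition RMSEs are returned.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(targets, dtype=float)
    if folds > y.size:
        raise ValueError(f"{folds} folds exceed {y.size} participants")
    rep_seeds = np.random.SeedSequence(seed).generate_state(reps) >> 1
    rmses = np.empty(reps)
    for r in range(reps):
        rs = int(rep_seeds[r])
        pred = np.empty_like(y)
        for train, test in KFold(n_splits=folds, shuffle=True, random_state=rs).split(X):
            model = RandomForestRegressor(random_state=rs, **(rf_params or {}))
            model.fit(X[train], y[train])
            pred[test] = model.predict(X[test])
        rmses[r] = np.sqrt(np.mean((pred - y) ** 2))
    se = float(rmses.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return ConditionResult(
        kind=kind, level=level, mean_rmse=float(rmses.mean()), se_rmse=se, n_reps=reps
    )


def _feature_matrix(records: list[PreprocessedRecord]) -> pd.DataFrame:
    rows = [extract_all(r) for r in records]
    return pd.DataFrame(rows, index=[r.id for r in records])


def _condition_seed(master: int, family: str, level: float, ) -> int:
    fam = _perturb.KINDS.index(family)
    return int(
        np.random.SeedSequence(
            [master, fam, 100_000 + int(round(level * 10000))]  # offset: level -1 marks unperturbed
        ).generate_state(1)[0]
        >> 1
    )


def run_experiment(config: ExperimentConfig) -> tuple[pd.DataFrame, dict]:
    """Run the full degradation experiment on a synthetic cohort.

    Returns a results table with one row per (family, condition) — level -1
    denoting the shared unperturbed condition — and a metadata dict recording
    seeds, forest defaults, the frozen feature set and the catalog version.
    """
    cohort = generate_cohort(seed=config.seed, config=config.cohort)
    records = [preprocess_record(r, config.trim_minutes) for r in cohort]
    cci = np.array([compute_cci(r).cci for r in records])
    base_rmse = baseline_rmse(cci)

    # feature matrices for every condition of every family
    unperturbed = _feature_matrix(records)
    matrices: dict[tuple[str, float], pd.DataFrame] = {}
    for family in config.families:
        for spec in condition_plan(family, config.grid_stride):
            if spec is None:
                continue
            cseed = _condition_seed(config.seed, family, spec.level)
            perturbed = [
                _perturb.apply_spec(
                    rec,
                    _perturb.PerturbationSpec(spec.kind, spec.level, seed=cseed + 7919 * i),
                )
                for i, rec in enumerate(records)
            ]
            matrices[(family, spec.level)] = _feature_matrix(perturbed)

    selected = preselect_features(
        unperturbed, cci, [unperturbed, *matrices.values()], config.alpha
    )

    rows = []
    unperturbed_result: ConditionResult | None = None
    for family in config.families:
        for spec in condition_plan(family, config.grid_stride):
            if spec is None:
                if unperturbed_result is None:
                    unperturbed_result = cv_rmse(
                        unperturbed[selected], cci, config.folds, config.reps,
                        seed=_condition_seed(config.seed, family, -1.0),
                        rf_params=config.rf_params, kind=family, level=-1.0,
                    )
                res = ConditionResult(
                    kind=family, level=-1.0,
                    mean_rmse=unperturbed_result.mean_rmse,
                    se_rmse=unperturbed_result.se_rmse,
                    n_reps=unperturbed_result.n_reps,
                )
            else:
                res = cv_rmse(
                    matrices[(family, spec.level)][selected], cci,
                    config.folds, config.reps,
                    seed=_condition_seed(config.seed, family, spec.level),
                    rf_params=config.rf_params, kind=family, level=spec.level,
                )
            rows.append(
                {
                    "family": res.kind,
                    "level": res.level,
                    "mean_rmse": res.mean_rmse,
                    "se_rmse": res.se_rmse,
                    "baseline_rmse": base_rmse,
                    "n_reps": res.n_reps,
                }
            )
    results = pd.DataFrame(rows)
    metadata = {
        "seed": config.seed,
        "n_participants": len(records),
        "folds": config.folds,
        "reps": config.reps,
        "alpha": config.alpha,
        "grid_stride": config.grid_stride,
        "catalog_version": CATALOG_VERSION,
        "selected_features": selected,
        "baseline_rmse": base_rmse,
        "rf_params": RandomForestRegressor(**config.rf_params).get_params(),
        "cci_targets": {r.id: float(c) for r, c in zip(records, cci)},
    }
    return results, metadata


def find_breakdown_level(
    levels: np.ndarray,
    mean_rmse: np.ndarray,
    baseline: float,
    smoothing: int = 3,
) -> float | None:
    """Smallest level where smoothed RMSE reaches the baseline and stays there.

    The RMSE curve (ordered by level) is smoothed with a centered moving
    average of ``smoothing`` points; the breakdown level is the first level
    at which the smoothed curve is >= baseline and remains so at every
    higher level.  Returns None if the model never loses predictive ability.
    """
    lv = np.asarray(levels, dtype=float)
    rm = np.asarray(mean_rmse, dtype=float)
    order = np.argsort(lv)
    lv, rm = lv[order], rm[order]
    half = smoothing // 2
    smoothed = np.array(
        [rm[max(0, i - half) : i + half + 1].mean() for i in range(rm.size)]
    )
    above = smoothed >= baseline
    # first index from which 'above' holds for all subsequent levels
    for i in range(above.size):
        if above[i:].all():
            return float(lv[i])
    return None
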