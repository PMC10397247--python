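"""Fitting pairwise interaction models by iterative realign-and-refit.

A measured interaction score is modelled as a linear function of the
contact counts of the pair at some heptad alignment.  Off-target pairs
need not interact in register, so the alignment itself is latent: the
fit alternates between (1) ordinary least squares on the contact counts
at the current alignment assignment and (2) re-assigning every
off-target pair to the alignment that the current model scores highest.
On-target pairs are pinned to the in-register alignment by default.
The loop stops at a fixed point of the assignment (typically within a
handful of iterations) or at ``max_iter``.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ccgen import CoiledCoil
from .scoring import (
    CONSEC_CLASS,
    INTERCEPT_KEY,
    PAIR_CLASSES,
    FeatureConfig,
    ScoringModel,
    enumerate_alignments,
    feature_vector,
    score_pair,
)

__all__ = [
    "TrainingSet",
    "FitReport",
    "build_design_matrix",
    "fit_weights",
    "iterative_fit",
    "bootstrap_evaluate",
    "evaluate_r2",
    "gauge_fix",
]


@dataclass
class TrainingSet:
    """Measured pair scores plus the coil registry needed to featurize them.

    ``data`` columns: ``idA``, ``idB``, ``score``, ``on_target`` (bool).
    """

    data: pd.DataFrame
    coils: Mapping[str, CoiledCoil]

    def __post_init__(self) -> None:
        required = {"idA", "idB", "score", "on_target"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"training table lacks columns {sorted(missing)}")
        if len(self.data) == 0:
            raise ValueError("training set is empty")
        unknown = (
            set(self.data["idA"]) | set(self.data["idB"])
        ) - set(self.coils)
        if unknown:
            raise KeyError(
                f"{len(unknown)} coil id(s) not in registry, "
                f"e.g. {sorted(unknown)[:3]}"
            )
        if not np.isfinite(self.data["score"].to_numpy(dtype=float)).all():
            raise ValueError("training scores must be finite")
        self.data = self.data.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @classmethod
    def from_tsv(cls, path, coils: Mapping[str, CoiledCoil]) -> "TrainingSet":
        df = pd.read_csv(path, sep="\t")
        df["on_target"] = df["on_target"].astype(bool)
        if "score" not in df.columns and "interaction_score" in df.columns:
            df = df.rename(columns={"interaction_score": "score"})
        return cls(df, coils)


@dataclass
class FitReport:
    model: ScoringModel
    n_iterations: int
    r2_train: float
    converged: bool
    bootstrap_r2: list[float] = field(default_factory=list)
    offsets: np.ndarray | None = None
    rss_history: list[float] = field(default_factory=list)


def _alignment_lookup(n_heptads: int, min_overlap: int):
    alns = enumerate_alignments(n_heptads, n_heptads, min_overlap)
    return {a.offset_heptads: a for a in alns}


def build_design_matrix(
    ts: TrainingSet,
    offsets: Sequence[int] | Mapping[tuple[str, str], int],
    config: FeatureConfig,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Contact-count design matrix at a given per-row alignment assignment.

    ``offsets`` is either one heptad offset per row or a mapping keyed
    by ``(idA, idB)``.  Columns are the union of feature keys over all
    rows (absent features are zero); the intercept column is always
    present and last.
    """
    rows = ts.data
    if isinstance(offsets, Mapping):
        off = [offsets[(r.idA, r.idB)] for r in rows.itertuples()]
    else:
        off = list(offsets)
        if len(off) != len(rows):
            raise ValueError("one offset per training row required")
    feats: list[dict[str, int]] = []
    lookup_cache: dict[int, dict[int, object]] = {}
    for r, k in zip(rows.itertuples(), off):
        A = ts.coils[r.idA]
        B = ts.coils[r.idB]
        key = (A.n_heptads, B.n_heptads)
        if key not in lookup_cache:
            lookup_cache[key] = {
                a.offset_heptads: a
                for a in enumerate_alignments(A.n_heptads, B.n_heptads, 1)
            }
        aln = lookup_cache[key].get(k)
        if aln is None:
            raise ValueError(f"offset {k} infeasible for pair {r.idA}/{r.idB}")
        feats.append(feature_vector(A, B, aln, config))
    cols = sorted({c for f in feats for c in f} - {INTERCEPT_KEY})
    cols.append(INTERCEPT_KEY)
    X = pd.DataFrame(
        [[f.get(c, 0) for c in cols] for f in feats],
        columns=cols,
        dtype=float,
    )
    y = rows["score"].to_numpy(dtype=float)
    return X, y


def _model_from_coefs(
    coefs: Mapping[str, float], config: FeatureConfig
) -> ScoringModel:
    pair_weights: dict[str, dict[str, float]] = {c: {} for c in PAIR_CLASSES}
    consec: dict[str, float] = {}
    intercept = 0.0
    for key, w in coefs.items():
        if key == INTERCEPT_KEY:
            intercept = float(w)
        else:
            cls, pk = key.split(":", 1)
            if cls == CONSEC_CLASS:
                consec[pk] = float(w)
            else:
                pair_weights[cls][pk] = float(w)
    return ScoringModel(
        pair_weights={c: t for c, t in pair_weights.items() if t},
        consecutive_a_weights=consec if config.use_consecutive_a else None,
        intercept=intercept,
        config=config,
    )


def fit_weights(
    X: pd.DataFrame,
    y: np.ndarray,
    ridge_lambda: float = 0.0,
    config: FeatureConfig | None = None,
) -> ScoringModel:
    """Least-squares (optionally ridge) weights for a contact-count design.

    The intercept column is never penalized.  With ``ridge_lambda == 0``
    a rank-deficient design falls back to the minimum-norm solution with
    a warning — e.g. when the library's d position is invariant, the dd
    contact count is collinear with the intercept and the split between
    them is arbitrary.
    """
    if ridge_lambda < 0:
        raise ValueError("ridge_lambda must be non-negative")
    config = config or FeatureConfig()
    Xm = X.to_numpy(dtype=float)
    n, p = Xm.shape
    if ridge_lambda > 0:
        penalty = np.eye(p) * ridge_lambda
        icol = list(X.columns).index(INTERCEPT_KEY)
        penalty[icol, icol] = 0.0
        beta = np.linalg.solve(Xm.T @ Xm + penalty, Xm.T @ y)
    else:
        beta, _, rank, _ = np.linalg.lstsq(Xm, y, rcond=None)
        if rank < p:
            warnings.warn(
                f"design matrix is rank-deficient (rank {rank} < {p} "
                "columns); returning the minimum-norm solution. "
                "Collinear weight classes (e.g. dd with an invariant d "
                "position) are not individually identifiable.",
                stacklevel=2,
            )
    return _model_from_coefs(dict(zip(X.columns, beta)), config)


def _r2(X: pd.DataFrame, y: np.ndarray, model: ScoringModel) -> float:
    pred = _predict(X, model)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0 if ss_res < 1e-12 * max(1.0, float(np.sum(y**2))) else 0.0
    return 1.0 - ss_res / ss_tot


def _predict(X: pd.DataFrame, model: ScoringModel) -> np.ndarray:
    m = model.with_missing_as_zero()
    w = np.array([m.weight(c) for c in X.columns])
    return X.to_numpy(dtype=float) @ w


def _realign(
    ts: TrainingSet,
    offsets: list[int],
    model: ScoringModel,
    pin_on_target: bool,
) -> list[int]:
    # newly-exposed residue pairs at a shifted alignment may lack a
    # fitted weight yet; treat them as zero during re-assignment
    m = model.with_missing_as_zero()
    new = []
    for r, k in zip(ts.data.itertuples(), offsets):
        if pin_on_target and r.on_target:
            new.append(0)
            continue
        _, best = score_pair(ts.coils[r.idA], ts.coils[r.idB], m)
        new.append(best)
    return new


def iterative_fit(
    ts: TrainingSet,
    config: FeatureConfig | None = None,
    max_iter: int = 20,
    ridge_lambda: float = 0.0,
    pin_on_target: bool = True,
) -> FitReport:
    """Alternate least-squares refits with off-target realignment.

    Every pair starts in register (offset 0).  Each round fits weights
    at the current assignment, then moves each off-target pair to its
    best-scoring alignment under the fitted model.  Convergence is a
    fixed point of the assignment; ``converged=False`` (not an error)
    is reported if ``max_iter`` rounds pass without one.  With shifting
    disabled in ``config`` the loop is a single plain fit.
    """
    config = config or FeatureConfig()
    offsets = [0] * len(ts)
    rss_history: list[float] = []
    model: ScoringModel | None = None
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        X, y = build_design_matrix(ts, offsets, config)
        model = fit_weights(X, y, ridge_lambda, config)
        rss_history.append(float(np.sum((y - _predict(X, model)) ** 2)))
        if not config.use_shifting:
            converged = True
            break
        new_offsets = _realign(ts, offsets, model, pin_on_target)
        if new_offsets == offsets:
            converged = True
            break
        offsets = new_offsets
    X, y = build_design_matrix(ts, offsets, config)
    return FitReport(
        model=model,
        n_iterations=n_iter,
        r2_train=_r2(X, y, model),
        converged=converged,
        offsets=np.asarray(offsets),
        rss_history=rss_history,
    )


def evaluate_r2(
    model: ScoringModel, ts: TrainingSet, realign: bool = True
) -> float:
    """Coefficient of determination of a model on (held-out) pairs.

    With ``realign=True`` each pair is scored at its best alignment
    under the model (inference mode); otherwise in register.
    """
    m = model.with_missing_as_zero()
    preds = []
    for r in ts.data.itertuples():
        A, B = ts.coils[r.idA], ts.coils[r.idB]
        if realign and model.config.use_shifting:
            s, _ = score_pair(A, B, m)
        else:
            aln0 = next(
                a
                for a in enumerate_alignments(A.n_heptads, B.n_heptads, 1)
                if a.offset_heptads == 0
            )
            fv = feature_vector(A, B, aln0, m.config)
            s = sum(m.weight(k) * v for k, v in fv.items())
        preds.append(s)
    y = ts.data["score"].to_numpy(dtype=float)
    pred = np.asarray(preds)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return 1.0 - float(np.sum((y - pred) ** 2)) / ss_tot


def gauge_fix(model: ScoringModel) -> ScoringModel:
    """Canonical representative of a model's prediction-equivalence class.

    Contact counts obey structural identities on every alignment of
    equal-length chains: the a- and d-contact totals both equal the
    overlap length, the g/e total equals ``2 * (overlap - 1)`` (as does
    the consecutive-a total), and exactly one a-contact is N-terminal.
    Adding a constant to all weights of one class can therefore be
    absorbed by the other classes and the intercept without changing
    any prediction — the raw weights are identifiable only up to this
    gauge.  This helper fixes the gauge by centering the g/e,
    consecutive-a and d/d weight classes at zero mean and aligning the
    N-terminal a-weights' mean with the core a-weights' mean, so that
    two prediction-equivalent models (e.g. a fit and the generator it
    recovered) become directly comparable weight by weight.
    """
    pw = {cls: dict(tab) for cls, tab in model.pair_weights.items()}
    ge = pw.get("ge", {})
    dd = pw.get("dd", {})
    core = pw.get("aa_core", {})
    nterm = pw.get("aa_nterm", {})
    consec = dict(model.consecutive_a_weights or {})

    beta = -float(np.mean(list(ge.values()))) if ge else 0.0
    delta = -float(np.mean(list(consec.values()))) if consec else 0.0
    alpha = (
        (float(np.mean(list(dd.values()))) if dd else 0.0) - 2 * beta - 2 * delta
    )
    gamma = (
        float(np.mean(list(core.values()))) - float(np.mean(list(nterm.values())))
        if nterm and core
        else 0.0
    )
    for k in ge:
        ge[k] += beta
    for k in consec:
        consec[k] += delta
    for k in dd:
        dd[k] -= alpha + 2 * beta + 2 * delta
    for k in core:
        core[k] += alpha
    for k in nterm:
        nterm[k] += alpha + gamma
    return ScoringModel(
        pair_weights=pw,
        consecutive_a_weights=consec if model.consecutive_a_weights else None,
        intercept=model.intercept + 2 * beta + 2 * delta - gamma,
        config=model.config,
        missing_weight=model.missing_weight,
    )


def bootstrap_evaluate(
    ts: TrainingSet,
    config: FeatureConfig | None = None,
    n_boot: int = 100,
    seed: int = 0,
    max_iter: int = 20,
    ridge_lambda: float = 0.0,
    heldout: TrainingSet | None = None,
) -> FitReport:
    """Bootstrap the realign-refit fit and record per-resample R².

    Rows are resampled with replacement ``n_boot`` times; each resample
    is refit from scratch and its R² recorded — on the resampled rows by
    default (comparing candidate model families), or on ``heldout``
    pairs when provided (generalization).  The report's model and
    training R² come from a final fit on the full data.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    config = config or FeatureConfig()
    rng = np.random.default_rng(seed)
    n = len(ts)
    boots: list[float] = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = TrainingSet(ts.data.iloc[idx].reset_index(drop=True), ts.coils)
        rep = iterative_fit(sub, config, max_iter, ridge_lambda)
        if heldout is not None:
            boots.append(evaluate_r2(rep.model, heldout))
        else:
            boots.append(rep.r2_train)
    full = iterative_fit(ts, config, max_iter, ridge_lambda)
    full.bootstrap_r2 = boots
    return full
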