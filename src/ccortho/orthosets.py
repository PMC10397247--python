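"""Orthogonality gaps and largest orthogonal subsets of interaction matrices.

An *orthogonal set* pairs proteins (hetero- or homodimers) so that each
member participates in exactly one on-target interaction and every
on-target interaction is stronger than every off-target interaction
among the members.  Its *orthogonality gap* is the weakest on-target
score minus the strongest off-target score; a set is orthogonal at gap
``g`` when that difference is at least ``g``.

The finder reduces subset selection to a maximum independent set: each
candidate on-target pair is a vertex, two vertices conflict when they
share a protein or induce an off-target interaction too strong for the
requested gap, and a maximum independent set of the conflict graph is
the largest pairing.  Because the pairwise conflict test can
overestimate the achievable global gap, the returned set is re-checked
against the raw scores and repaired (weakest pair dropped) until the
gap condition holds exactly.
"""
from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .scoring import ScoringModel, score_matrix

__all__ = [
    "Pairing",
    "OrthogonalSet",
    "MeasuredMatrix",
    "SymmetricScores",
    "MissingScoreError",
    "symmetrize",
    "orthogonality_gap",
    "find_largest_orthogonal_subset",
    "gap_size_profile",
    "design_orthogonal_sets",
]

EXACT_PROTEIN_LIMIT = 40


class MissingScoreError(KeyError):
    """A score needed for a gap computation was measured in no orientation."""


def _canon(i: str, j: str) -> tuple[str, str]:
    return (i, j) if i <= j else (j, i)


@dataclass(frozen=True)
class Pairing:
    """A set of on-target pairs; homodimers ``(x, x)`` are allowed.

    Every member protein appears in exactly one pair.
    """

    pairs: tuple[tuple[str, str], ...]

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        canon = tuple(sorted(_canon(*p) for p in pairs))
        object.__setattr__(self, "pairs", canon)
        seen: set[str] = set()
        for i, j in canon:
            members = {i, j}
            if seen & members:
                raise ValueError(
                    f"protein {sorted(seen & members)} appears in more than "
                    "one on-target pair"
                )
            seen |= members

    @property
    def members(self) -> tuple[str, ...]:
        out: set[str] = set()
        for i, j in self.pairs:
            out |= {i, j}
        return tuple(sorted(out))

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class OrthogonalSet:
    pairing: Pairing
    gap: float
    n_on_target: int
    min_on_target_score: float
    max_off_target_score: float

    @property
    def unbounded(self) -> bool:
        """True when the set has no off-target interactions (gap is +inf)."""
        return math.isinf(self.gap)


@dataclass
class MeasuredMatrix:
    """Possibly asymmetric, possibly incomplete pairwise measurements.

    ``data`` holds long-format rows (idA, idB, score); both orientations
    of a pair may be present (the assay tags each protein with one half
    of the reporter, so (A,B) and (B,A) are distinct measurements).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"idA", "idB", "score"}
        if not required <= set(self.data.columns):
            raise ValueError(f"measured matrix needs columns {sorted(required)}")

    @property
    def proteins(self) -> list[str]:
        return sorted(set(self.data["idA"]) | set(self.data["idB"]))

    def square(self) -> pd.DataFrame:
        """Oriented square table (rows = idA) with NaN for unmeasured."""
        ids = self.proteins
        M = pd.DataFrame(np.nan, index=ids, columns=ids)
        for r in self.data.itertuples():
            M.at[r.idA, r.idB] = r.score
        return M

    @classmethod
    def from_square(cls, df: pd.DataFrame) -> "MeasuredMatrix":
        rows = [
            {"idA": a, "idB": b, "score": df.at[a, b]}
            for a in df.index
            for b in df.columns
            if not pd.isna(df.at[a, b])
        ]
        return cls(pd.DataFrame(rows))


@dataclass(frozen=True)
class SymmetricScores:
    """Symmetric views of a measured matrix for gap evaluation.

    ``on`` scores on-target pairs and ``off`` scores off-target pairs;
    under the entrywise policies they coincide, under the conservative
    policy ``on`` takes the weaker and ``off`` the stronger orientation,
    so reported gaps never flatter the measurement.
    """

    on: pd.DataFrame
    off: pd.DataFrame

    @property
    def proteins(self) -> list[str]:
        return list(self.on.index)

    def _get(self, table: pd.DataFrame, i: str, j: str) -> float:
        try:
            v = table.at[i, j]
        except KeyError:
            raise MissingScoreError(f"no measurement for pair ({i}, {j})")
        if pd.isna(v):
            raise MissingScoreError(
                f"pair ({i}, {j}) measured in neither orientation"
            )
        return float(v)

    def on_score(self, i: str, j: str) -> float:
        return self._get(self.on, i, j)

    def off_score(self, i: str, j: str) -> float:
        return self._get(self.off, i, j)


def symmetrize(
    m: MeasuredMatrix | pd.DataFrame, policy: str = "mean"
) -> SymmetricScores:
    """Collapse the two orientations of each pair into symmetric tables.

    Policies ``mean``/``min``/``max`` combine entrywise (falling back to
    the present orientation when only one was measured).  The
    ``conservative`` policy uses the orientation minimum for on-target
    evaluation and the maximum for off-target evaluation, which can only
    shrink any reported gap relative to ``mean``.
    """
    if isinstance(m, pd.DataFrame):
        M = m.copy()
    else:
        M = m.square()
    T = M.T
    both = np.stack([M.to_numpy(dtype=float), T.to_numpy(dtype=float)])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        lo = np.nanmin(both, axis=0)
        hi = np.nanmax(both, axis=0)
        mid = np.nanmean(both, axis=0)
    ids = M.index
    frames = {
        "min": pd.DataFrame(lo, index=ids, columns=ids),
        "max": pd.DataFrame(hi, index=ids, columns=ids),
        "mean": pd.DataFrame(mid, index=ids, columns=ids),
    }
    if policy in frames:
        return SymmetricScores(on=frames[policy], off=frames[policy])
    if policy == "conservative":
        return SymmetricScores(on=frames["min"], off=frames["max"])
    raise ValueError(
        f"unknown policy {policy!r}; expected mean|min|max|conservative"
    )


def _as_scores(scores) -> SymmetricScores:
    if isinstance(scores, SymmetricScores):
        return scores
    if isinstance(scores, pd.DataFrame):
        return SymmetricScores(on=scores, off=scores)
    if isinstance(scores, MeasuredMatrix):
        return symmetrize(scores, "mean")
    raise TypeError(f"cannot interpret {type(scores)!r} as a score table")


def orthogonality_gap(scores, pairing: Pairing) -> OrthogonalSet:
    """Gap of a given pairing: weakest on-target minus strongest off-target.

    Off-target interactions are every unordered pair among the members
    (including non-designated homodimers) that is not an on-target pair.
    A pairing with no off-target interactions — a single homodimer —
    has an unbounded (+inf) gap.
    """
    sc = _as_scores(scores)
    if len(pairing) == 0:
        return OrthogonalSet(pairing, math.inf, 0, math.inf, -math.inf)
    on = [sc.on_score(i, j) for i, j in pairing.pairs]
    members = pairing.members
    on_set = set(pairing.pairs)
    off = [
        sc.off_score(i, j)
        for i, j in itertools.combinations_with_replacement(members, 2)
        if _canon(i, j) not in on_set
    ]
    min_on = min(on)
    max_off = max(off) if off else -math.inf
    return OrthogonalSet(
        pairing=pairing,
        gap=min_on - max_off,
        n_on_target=len(pairing),
        min_on_target_score=min_on,
        max_off_target_score=max_off,
    )


def _candidate_pairs(sc: SymmetricScores) -> list[tuple[str, str]]:
    ids = sc.proteins
    out = []
    for i, j in itertools.combinations_with_replacement(ids, 2):
        if not pd.isna(sc.on.at[i, j]):
            out.append((i, j))
    return out


def _internally_viable(
    sc: SymmetricScores, pair: tuple[str, str], threshold: float
) -> bool:
    i, j = pair
    if i == j:
        return True
    on = sc.on_score(i, j)
    return (
        sc.off_score(i, i) <= on - threshold
        and sc.off_score(j, j) <= on - threshold
    )


def _internally_viable_floor(
    sc: SymmetricScores, pair: tuple[str, str], ceiling: float
) -> bool:
    i, j = pair
    if i == j:
        return True
    return sc.off_score(i, i) <= ceiling and sc.off_score(j, j) <= ceiling


def _conflict_floor(
    sc: SymmetricScores,
    p: tuple[str, str],
    q: tuple[str, str],
    ceiling: float,
) -> bool:
    if set(p) & set(q):
        return True
    for x in set(p):
        for y in set(q):
            if sc.off_score(x, y) > ceiling:
                return True
    return False


def _repair(sc: SymmetricScores, pairs: list[tuple[str, str]], threshold: float):
    """Drop weakest on-target pairs until the global gap condition holds."""
    pairs = sorted(pairs)
    while pairs:
        result = orthogonality_gap(sc, Pairing(pairs))
        if result.gap >= threshold:
            return result
        weakest = min(pairs, key=lambda p: (sc.on_score(*p), p))
        pairs.remove(weakest)
    return orthogonality_gap(sc, Pairing(()))


def _improve_gap(
    sc: SymmetricScores,
    chosen: list[tuple[str, str]],
    candidates: list[tuple[str, str]],
    threshold: float,
) -> list[tuple[str, str]]:
    """Size-preserving local swaps that strictly increase the global gap."""
    current = orthogonality_gap(sc, Pairing(chosen)).gap
    improved = True
    while improved:
        improved = False
        for out_pair in list(chosen):
            rest = [p for p in chosen if p != out_pair]
            for cand in candidates:
                if cand == out_pair or any(set(cand) & set(p) for p in rest):
                    continue
                trial = rest + [cand]
                gap = orthogonality_gap(sc, Pairing(trial)).gap
                if gap > current + 1e-12 and gap >= threshold:
                    chosen = sorted(trial)
                    current = gap
                    improved = True
                    break
            if improved:
                break
    return chosen


def _mis_pairs(
    sc: SymmetricScores,
    candidates: list[tuple[str, str]],
    ceiling: float,
    exact: bool,
) -> list[tuple[str, str]]:
    """Maximum independent set of the conflict graph at a uniform
    off-target ceiling."""
    G = nx.Graph()
    G.add_nodes_from(range(len(candidates)))
    for u, v in itertools.combinations(range(len(candidates)), 2):
        if _conflict_floor(sc, candidates[u], candidates[v], ceiling):
            G.add_edge(u, v)
    if exact:
        clique, _ = nx.max_weight_clique(nx.complement(G), weight=None)
        return sorted(candidates[u] for u in clique)
    order = sorted(
        range(len(candidates)),
        key=lambda u: (-sc.on_score(*candidates[u]), candidates[u]),
    )
    chosen_idx: list[int] = []
    for u in order:
        if all(not G.has_edge(u, v) for v in chosen_idx):
            chosen_idx.append(u)
    return sorted(candidates[u] for u in chosen_idx)


def find_largest_orthogonal_subset(
    scores, gap_threshold: float = 1.0, exact_limit: int = EXACT_PROTEIN_LIMIT
) -> OrthogonalSet:
    """Largest pairing whose orthogonality gap meets ``gap_threshold``.

    The global gap condition couples every off-target interaction to
    the *weakest* on-target score of the whole set, so a single
    pairwise conflict test is not exact.  The search therefore guesses
    that weakest on-target score ``v`` over all candidate values: at a
    fixed ``v`` the condition is a uniform off-target ceiling
    ``v - gap_threshold``, the conflict graph encodes it exactly, and a
    maximum independent set of that graph (exact branch-and-bound
    maximum clique on the complement for up to ``exact_limit`` proteins,
    greedy with local search above, with a warning) is the largest
    pairing with min on-target >= ``v``.  The best solution over all
    ``v`` — preferring size, then recomputed gap, then lexicographic
    pair ids — is returned; a lone homodimer (no off-target
    interactions, unbounded gap) meets any threshold.
    """
    sc = _as_scores(scores)
    all_candidates = _candidate_pairs(sc)
    if not all_candidates:
        return orthogonality_gap(sc, Pairing(()))
    exact = len(sc.proteins) <= exact_limit
    if not exact:
        warnings.warn(
            f"{len(sc.proteins)} proteins exceeds the exact-search limit "
            f"({exact_limit}); using a greedy heuristic with local search — "
            "the returned set is valid but may not be maximum",
            stacklevel=2,
        )
    floors = sorted(
        {sc.on_score(*p) for p in all_candidates}, reverse=True
    )
    best: OrthogonalSet | None = None
    for v in floors:
        ceiling = v - gap_threshold
        cands = [
            p
            for p in all_candidates
            if sc.on_score(*p) >= v
            and _internally_viable_floor(sc, p, ceiling)
        ]
        if not cands:
            continue
        if best is not None and len(cands) < best.n_on_target:
            continue  # cannot beat the incumbent size
        chosen = _mis_pairs(sc, cands, ceiling, exact)
        if not chosen:
            continue
        result = orthogonality_gap(sc, Pairing(chosen))
        if (
            best is None
            or result.n_on_target > best.n_on_target
            or (
                result.n_on_target == best.n_on_target
                and (
                    result.gap > best.gap
                    or (
                        result.gap == best.gap
                        and result.pairing.pairs < best.pairing.pairs
                    )
                )
            )
        ):
            best = result
    if best is None:
        return orthogonality_gap(sc, Pairing(()))
    chosen = _improve_gap(
        sc, list(best.pairing.pairs), all_candidates, gap_threshold
    )
    return _repair(sc, chosen, gap_threshold)


def gap_size_profile(scores, thresholds: Sequence[float]):
    """Largest subset per gap threshold, and best observed gap per size.

    Returns ``(by_threshold, by_size)`` data frames: one row per
    requested threshold with the maximum achievable number of on-target
    pairs and the recomputed gap of that set; and, per subset size ``k``
    up to the overall maximum, the largest gap among returned sets of at
    least ``k`` pairs.
    """
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    sc = _as_scores(scores)
    sets = []
    rows = []
    for t in thresholds:
        s = find_largest_orthogonal_subset(sc, t)
        sets.append(s)
        rows.append(
            {
                "threshold": t,
                "max_n_on_target": s.n_on_target,
                "gap": s.gap,
            }
        )
    by_threshold = pd.DataFrame(rows)
    max_k = max((s.n_on_target for s in sets), default=0)
    size_rows = []
    for k in range(1, max_k + 1):
        gaps = [s.gap for s in sets if s.n_on_target >= k]
        size_rows.append({"size": k, "best_gap": max(gaps)})
    by_size = pd.DataFrame(size_rows, columns=["size", "best_gap"])
    return by_threshold, by_size


def design_orthogonal_sets(
    library,
    model: ScoringModel,
    target_n_sets: int = 1,
    max_proteins_per_set: int = 12,
    gap_threshold: float = 0.0,
) -> list[OrthogonalSet]:
    """Predict disjoint orthogonal sets for a scored library.

    Scores the library all-against-all with ``model``, then repeatedly
    pools the strongest-interacting proteins (up to
    ``max_proteins_per_set``), runs the exact subset finder on the pool,
    and removes the chosen members before the next round.  Every
    returned set satisfies the predicted gap threshold by construction.
    """
    scores = score_matrix(list(library), model)
    remaining = list(scores.index)
    out: list[OrthogonalSet] = []
    for _ in range(target_n_sets):
        if not remaining:
            break
        sub = scores.loc[remaining, remaining]
        # pool the proteins involved in the strongest candidate pairs
        best_per_protein = sub.max(axis=1).sort_values(
            ascending=False, kind="mergesort"
        )
        pool = list(best_per_protein.index[:max_proteins_per_set])
        pool_scores = scores.loc[pool, pool]
        found = find_largest_orthogonal_subset(pool_scores, gap_threshold)
        if found.n_on_target == 0:
            break
        out.append(found)
        used = set(found.pairing.members)
        remaining = [p for p in remaining if p not in used]
    return out


def sets_to_table(sets: Sequence[OrthogonalSet]) -> pd.DataFrame:
    """Flatten orthogonal sets to a report table (one row per set)."""
    rows = []
    for idx, s in enumerate(sets):
        rows.append(
            {
                "set_id": idx,
                "members": ";".join(s.pairing.members),
                "pairs": ";".join(f"{i}:{j}" for i, j in s.pairing.pairs),
                "gap": s.gap,
                "n_on_target": s.n_on_target,
            }
        )
    return pd.DataFrame(
        rows, columns=["set_id", "members", "pairs", "gap", "n_on_target"]
    )
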