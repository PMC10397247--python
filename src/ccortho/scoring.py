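"""Linear interaction scoring of parallel coiled-coil dimers.

The interaction score of two parallel chains is a sum of learned
weights over residue pairs at the dimer interface, in the style of
pairwise coiled-coil potentials:

* ``aa`` — hydrophobic-core contact between the ``a`` residues of
  aligned heptads.  With the N-terminal variant enabled, the first
  ``a``–``a'`` contact of the interface (where helix fraying occurs) is
  scored by a separate ``aa_nterm`` weight class.
* ``dd`` — core contact between aligned ``d`` residues.
* ``ge`` — inter-helical electrostatic contact between ``g`` of heptad
  *i* on one chain and ``e'`` of heptad *i*+1 on the other; both the
  ``g``–``e'`` and ``e``–``g'`` orientations share one weight class.
* optionally, within-chain weights for consecutive ``a`` residues.

Chains may interact out of register by a whole number of heptads
("heptad shift"), leaving a shorter overlapping interface; the score of
a pair is the maximum over all such alignments.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ccgen import CoiledCoil

PAIR_CLASSES = ("aa_core", "aa_nterm", "dd", "ge")
CONSEC_CLASS = "aconsec"
INTERCEPT_KEY = "intercept"

__all__ = [
    "PAIR_CLASSES",
    "CONSEC_CLASS",
    "INTERCEPT_KEY",
    "InterfaceAlignment",
    "FeatureConfig",
    "ScoringModel",
    "ScoringError",
    "EmptyAlignmentDomainError",
    "pair_key",
    "enumerate_alignments",
    "feature_vector",
    "score_alignment",
    "score_pair",
    "score_matrix",
    "matrix_to_long",
]


class ScoringError(ValueError):
    """Scoring failed (register mismatch, missing weight, ...)."""


class EmptyAlignmentDomainError(ScoringError):
    """No alignment satisfies the requested minimum overlap."""


def pair_key(r1: str, r2: str) -> str:
    """Canonical unordered residue-pair key, e.g. ``pair_key('K','E') == 'EK'``."""
    return r1 + r2 if r1 <= r2 else r2 + r1


@dataclass(frozen=True)
class InterfaceAlignment:
    """Relative heptad offset of chain B against chain A.

    ``offset_heptads = k`` means heptad ``j`` of B sits against heptad
    ``j + k`` of A, so the overlapping interface pairs heptads
    ``(h, h - k)`` for ``h`` in the overlap window of A.
    """

    offset_heptads: int
    overlap: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.overlap:
            raise ScoringError("alignment must overlap in at least one heptad")
        k = self.offset_heptads
        for hA, hB in self.overlap:
            if hA - hB != k:
                raise ScoringError(
                    f"overlap pair ({hA},{hB}) inconsistent with offset {k}"
                )

    def __len__(self) -> int:
        return len(self.overlap)


def enumerate_alignments(
    n_heptads_A: int, n_heptads_B: int, min_overlap: int = 1
) -> list[InterfaceAlignment]:
    """All whole-heptad alignments with at least ``min_overlap`` heptads.

    Returned in ascending offset order; offset 0 (in register) is always
    included when feasible.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    if min_overlap > min(n_heptads_A, n_heptads_B):
        raise EmptyAlignmentDomainError(
            f"min_overlap={min_overlap} exceeds the shorter chain "
            f"({min(n_heptads_A, n_heptads_B)} heptads)"
        )
    out = []
    for k in range(-(n_heptads_B - 1), n_heptads_A):
        lo = max(0, k)
        hi = min(n_heptads_A, n_heptads_B + k)
        if hi - lo >= min_overlap:
            out.append(
                InterfaceAlignment(
                    offset_heptads=k,
                    overlap=tuple((h, h - k) for h in range(lo, hi)),
                )
            )
    return out


@dataclass(frozen=True)
class FeatureConfig:
    """Which interface features a model uses.

    ``nterm_chain_start=False`` (default) classifies the first a-a'
    contact *of the overlapping interface* as N-terminal; ``True``
    instead marks contacts involving heptad 0 of either chain.
    """

    use_nterm: bool = True
    use_consecutive_a: bool = False
    use_shifting: bool = True
    min_overlap: int = 1
    nterm_chain_start: bool = False


def feature_vector(
    A: CoiledCoil,
    B: CoiledCoil,
    aln: InterfaceAlignment,
    config: FeatureConfig,
) -> dict[str, int]:
    """Integer contact counts for one alignment of a chain pair.

    Keys are ``"<class>:<pair>"`` strings (``"aa_core:II"``,
    ``"ge:EK"``, ...) plus a constant ``"intercept"`` feature.  The
    total number of a-position contacts always equals the overlap
    length, and the number of g/e contacts equals ``2 * (overlap - 1)``.
    """
    aA, dA = A.residues_at("a"), A.residues_at("d")
    eA, gA = A.residues_at("e"), A.residues_at("g")
    aB, dB = B.residues_at("a"), B.residues_at("d")
    eB, gB = B.residues_at("e"), B.residues_at("g")

    counts: dict[str, int] = {}

    def bump(cls: str, r1: str, r2: str) -> None:
        key = f"{cls}:{pair_key(r1, r2)}"
        counts[key] = counts.get(key, 0) + 1

    for idx, (hA, hB) in enumerate(aln.overlap):
        if config.use_nterm:
            if config.nterm_chain_start:
                is_nterm = hA == 0 or hB == 0
            else:
                is_nterm = idx == 0
        else:
            is_nterm = False
        bump("aa_nterm" if is_nterm else "aa_core", aA[hA], aB[hB])
        bump("dd", dA[hA], dB[hB])

    for (hA, hB), (hA2, hB2) in itertools.pairwise(aln.overlap):
        bump("ge", gA[hA], eB[hB2])  # g_i - e'_{i+1}
        bump("ge", eA[hA2], gB[hB])  # e_{i+1} - g'_i

    if config.use_consecutive_a:
        for (hA, _), (hA2, _) in itertools.pairwise(aln.overlap):
            bump(CONSEC_CLASS, aA[hA], aA[hA2])
        for (_, hB), (_, hB2) in itertools.pairwise(aln.overlap):
            bump(CONSEC_CLASS, aB[hB], aB[hB2])

    counts[INTERCEPT_KEY] = 1
    return counts


@dataclass
class ScoringModel:
    """Pairwise-weight linear model for coiled-coil interaction scores.

    ``pair_weights`` maps a weight class (``aa_core``, ``aa_nterm``,
    ``dd``, ``ge``) to a dict of canonical residue-pair keys.  Weights
    are symmetric in the residue pair by construction of the key.
    A residue pair encountered during scoring without a weight raises
    :class:`ScoringError` by default (``missing_weight="zero"`` treats
    it as 0 instead).
    """

    pair_weights: dict[str, dict[str, float]]
    consecutive_a_weights: dict[str, float] | None = None
    intercept: float = 0.0
    config: FeatureConfig = field(default_factory=FeatureConfig)
    missing_weight: str = "error"  # "error" | "zero"

    def __post_init__(self) -> None:
        for cls in self.pair_weights:
            if cls not in PAIR_CLASSES:
                raise ValueError(f"unknown weight class {cls!r}")
        for cls, table in self.pair_weights.items():
            for key in table:
                if key != pair_key(key[0], key[1]):
                    raise ValueError(
                        f"{cls} weight key {key!r} is not in canonical "
                        "sorted form"
                    )
        if self.missing_weight not in ("error", "zero"):
            raise ValueError("missing_weight must be 'error' or 'zero'")

    def weight(self, feature: str) -> float:
        """Weight of one feature key (``"<class>:<pair>"`` or intercept)."""
        if feature == INTERCEPT_KEY:
            return self.intercept
        cls, pk = feature.split(":", 1)
        if cls == CONSEC_CLASS:
            table = self.consecutive_a_weights or {}
        else:
            table = self.pair_weights.get(cls, {})
        if pk in table:
            return table[pk]
        if self.missing_weight == "zero":
            return 0.0
        raise ScoringError(
            f"no weight for residue pair {pk!r} in class {cls!r}; "
            "set missing_weight='zero' to ignore"
        )

    def with_missing_as_zero(self) -> "ScoringModel":
        return replace(self, missing_weight="zero")

    # -- JSON round-trip ---------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            "pair_weights": {
                cls: dict(sorted(tab.items()))
                for cls, tab in self.pair_weights.items()
            },
            "intercept": self.intercept,
            "use_nterm": self.config.use_nterm,
            "use_consecutive_a": self.config.use_consecutive_a,
            "use_shifting": self.config.use_shifting,
            "min_overlap": self.config.min_overlap,
            "nterm_chain_start": self.config.nterm_chain_start,
        }
        if self.consecutive_a_weights is not None:
            out["consecutive_a_weights"] = dict(
                sorted(self.consecutive_a_weights.items())
            )
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScoringModel":
        config = FeatureConfig(
            use_nterm=bool(d.get("use_nterm", True)),
            use_consecutive_a=bool(d.get("use_consecutive_a", False)),
            use_shifting=bool(d.get("use_shifting", True)),
            min_overlap=int(d.get("min_overlap", 1)),
            nterm_chain_start=bool(d.get("nterm_chain_start", False)),
        )
        return cls(
            pair_weights={
                k: dict(v) for k, v in d.get("pair_weights", {}).items()
            },
            consecutive_a_weights=(
                dict(d["consecutive_a_weights"])
                if "consecutive_a_weights" in d
                else None
            ),
            intercept=float(d.get("intercept", 0.0)),
            config=config,
        )

    @classmethod
    def from_json(cls, path) -> "ScoringModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def score_alignment(
    A: CoiledCoil, B: CoiledCoil, aln: InterfaceAlignment, model: ScoringModel
) -> float:
    """Dot product of the alignment's contact counts with model weights."""
    fv = feature_vector(A, B, aln, model.config)
    return float(sum(model.weight(k) * n for k, n in fv.items()))


def _offset_tie_order(alignments: Iterable[InterfaceAlignment]):
    # ties between equal-scoring alignments resolve to the smallest
    # |offset|, negative before positive — keeps in-register preferred
    return sorted(
        alignments, key=lambda a: (abs(a.offset_heptads), a.offset_heptads)
    )


def score_pair(
    A: CoiledCoil, B: CoiledCoil, model: ScoringModel
) -> tuple[float, int]:
    """Interaction score of a chain pair and the heptad offset attaining it.

    With shifting enabled the score is the maximum over all whole-heptad
    alignments with at least ``min_overlap`` heptads of interface;
    otherwise the in-register (offset 0) score.
    """
    if not model.config.use_shifting:
        aln0 = next(
            a
            for a in enumerate_alignments(A.n_heptads, B.n_heptads, 1)
            if a.offset_heptads == 0
        )
        return score_alignment(A, B, aln0, model), 0
    best_score = -np.inf
    best_offset = 0
    for aln in _offset_tie_order(
        enumerate_alignments(A.n_heptads, B.n_heptads, model.config.min_overlap)
    ):
        s = score_alignment(A, B, aln, model)
        if s > best_score:
            best_score, best_offset = s, aln.offset_heptads
    return best_score, best_offset


# ---------------------------------------------------------------------------
# Vectorized all-against-all scoring

def _encode(library: Sequence[CoiledCoil], cls: str):
    """Integer-code the residues of one register position across a library."""
    rows = [coil.residues_at(cls) for coil in library]
    letters = sorted(set("".join(rows)))
    index = {c: i for i, c in enumerate(letters)}
    codes = np.array([[index[c] for c in row] for row in rows], dtype=np.intp)
    return codes, letters


def _weight_matrix(
    model: ScoringModel, cls: str, letters: Sequence[str]
) -> np.ndarray:
    if cls == CONSEC_CLASS:
        table = model.consecutive_a_weights or {}
    else:
        table = model.pair_weights.get(cls, {})
    k = len(letters)
    W = np.full((k, k), np.nan)
    for i, r1 in enumerate(letters):
        for j, r2 in enumerate(letters):
            pk = pair_key(r1, r2)
            if pk in table:
                W[i, j] = table[pk]
            elif model.missing_weight == "zero":
                W[i, j] = 0.0
    return W


def score_matrix(
    library: Sequence[CoiledCoil],
    model: ScoringModel,
    return_offsets: bool = False,
):
    """All-against-all interaction scores for a library.

    Returns a symmetric ``n x n`` :class:`pandas.DataFrame` indexed by
    coil ids (and, optionally, the best heptad offset per pair).  The
    computation is vectorized over the library: for each candidate
    offset the contact-weight lookups are broadcast across all pairs at
    once, so the full 4,096-coil default library (16.7 million ordered
    scores) evaluates in minutes on one core.
    """
    if not library:
        raise ValueError("library is empty")
    n_heptads = library[0].n_heptads
    if any(c.n_heptads != n_heptads for c in library):
        # mixed-length libraries fall back to the per-pair path
        return _score_matrix_slow(library, model, return_offsets)
    ids = [c.id for c in library]
    if len(set(ids)) != len(ids):
        raise ValueError("library contains duplicate coil ids")

    codes = {}
    letters = {}
    for cls in "adeg":
        codes[cls], letters[cls] = _encode(library, cls)

    cfg = model.config
    W = {
        "aa_core": _weight_matrix(model, "aa_core", letters["a"]),
        "aa_nterm": _weight_matrix(model, "aa_nterm", letters["a"]),
        "dd": _weight_matrix(model, "dd", letters["d"]),
    }
    # ge lookups mix the g and e alphabets; build a joint alphabet
    ge_letters = sorted(set(letters["g"]) | set(letters["e"]))
    ge_index = {c: i for i, c in enumerate(ge_letters)}
    W_ge = _weight_matrix(model, "ge", ge_letters)
    g_codes = np.array(
        [[ge_index[c] for c in coil.residues_at("g")] for coil in library],
        dtype=np.intp,
    )
    e_codes = np.array(
        [[ge_index[c] for c in coil.residues_at("e")] for coil in library],
        dtype=np.intp,
    )
    W_ca = (
        _weight_matrix(model, CONSEC_CLASS, letters["a"])
        if cfg.use_consecutive_a
        else None
    )

    alignments = enumerate_alignments(
        n_heptads, n_heptads, cfg.min_overlap if cfg.use_shifting else n_heptads
    )
    if not cfg.use_shifting:
        alignments = [a for a in alignments if a.offset_heptads == 0]
    n = len(library)
    best = np.full((n, n), -np.inf)
    best_off = np.zeros((n, n), dtype=np.int16)

    for aln in _offset_tie_order(alignments):
        S = np.full((n, n), model.intercept)
        for idx, (hA, hB) in enumerate(aln.overlap):
            if cfg.use_nterm:
                if cfg.nterm_chain_start:
                    is_nterm = hA == 0 or hB == 0
                else:
                    is_nterm = idx == 0
            else:
                is_nterm = False
            Waa = W["aa_nterm"] if is_nterm else W["aa_core"]
            S += Waa[codes["a"][:, hA]][:, codes["a"][:, hB]]
            S += W["dd"][codes["d"][:, hA]][:, codes["d"][:, hB]]
        for (hA, hB), (hA2, hB2) in itertools.pairwise(aln.overlap):
            S += W_ge[g_codes[:, hA]][:, e_codes[:, hB2]]
            S += W_ge[e_codes[:, hA2]][:, g_codes[:, hB]]
        if W_ca is not None:
            rowc = np.zeros(n)
            colc = np.zeros(n)
            for (hA, _), (hA2, _) in itertools.pairwise(aln.overlap):
                rowc += W_ca[codes["a"][:, hA], codes["a"][:, hA2]]
            for (_, hB), (_, hB2) in itertools.pairwise(aln.overlap):
                colc += W_ca[codes["a"][:, hB], codes["a"][:, hB2]]
            S += rowc[:, None] + colc[None, :]
        if np.isnan(S).any():
            raise ScoringError(
                "a residue pair in the library has no weight in the model "
                f"(offset {aln.offset_heptads}); set missing_weight='zero' "
                "to ignore"
            )
        improved = S > best
        best = np.where(improved, S, best)
        best_off[improved] = aln.offset_heptads

    scores = pd.DataFrame(best, index=ids, columns=ids)
    if return_offsets:
        offsets = pd.DataFrame(best_off, index=ids, columns=ids)
        return scores, offsets
    return scores


def _score_matrix_slow(library, model, return_offsets):
    ids = [c.id for c in library]
    n = len(library)
    S = np.zeros((n, n))
    O = np.zeros((n, n), dtype=np.int16)
    for i in range(n):
        for j in range(i, n):
            s, k = score_pair(library[i], library[j], model)
            S[i, j] = S[j, i] = s
            O[i, j] = k
            O[j, i] = -k
    scores = pd.DataFrame(S, index=ids, columns=ids)
    if return_offsets:
        return scores, pd.DataFrame(O, index=ids, columns=ids)
    return scores


def matrix_to_long(
    scores: pd.DataFrame, offsets: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Flatten a square score table to (idA, idB, score[, best_offset]) rows."""
    rows = []
    ids = list(scores.index)
    for i, a in enumerate(ids):
        for b in ids[i:]:
            row = {"idA": a, "idB": b, "score": scores.at[a, b]}
            if offsets is not None:
                row["best_offset"] = int(offsets.at[a, b])
            rows.append(row)
    return pd.DataFrame(rows)
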