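"""Synthetic fixtures: ground-truth models, noisy interaction data,
planted orthogonal matrices, and barcode-level sequencing counts.

Every generator is deterministic under its seed.  The barcode simulator
mirrors the reporter-assay structure that the quantification pipeline
assumes: each protein pair carries several unique 20-nt barcodes, DNA
(plasmid) counts are negative-binomial around a target depth, and RNA
counts are negative-binomial with mean ``DNA x exp(interaction score)``,
so the ln-median RNA/DNA statistic recovers the planted score by
construction.  Emitted reads carry independent per-base substitution
errors for exercising extraction and error-collapsing.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .ccgen import Background, CoiledCoil, LibrarySpec, enumerate_library
from .orthosets import MeasuredMatrix, Pairing
from .quant import BarcodeCountTable, BarcodeMap
from .scoring import (
    FeatureConfig,
    ScoringModel,
    enumerate_alignments,
    pair_key,
    score_alignment,
    score_pair,
)
from .training import TrainingSet

__all__ = [
    "SynthConfig",
    "SimulatedAssay",
    "make_true_model",
    "random_coils",
    "simulate_interactions",
    "simulate_barcode_data",
    "plant_orthogonal_matrix",
    "preset_cc0_like",
]

DEFAULT_ALPHABETS: dict[str, str] = {"a": "IN", "d": "L", "e": "EK", "g": "EK"}


@dataclass(frozen=True)
class SynthConfig:
    """Knobs of the synthetic assay.

    Defaults emulate the assay conditions the pipeline targets:
    measurement noise of 0.15 log-units (consistent with replicate
    correlations above 0.98 and worst-case score uncertainty below
    0.8 over a multi-log-unit dynamic range), several barcodes per
    cloned construct, ~100 DNA reads per barcode, moderately
    overdispersed counts and a 0.5% per-base sequencing error rate.
    """

    seed: int = 0
    library_spec: LibrarySpec = field(default_factory=LibrarySpec)
    noise_sd: float = 0.15
    barcodes_per_pair: int = 8
    dna_depth: float = 100.0
    rna_dispersion: float = 20.0
    error_rate: float = 0.005
    n_replicates: int = 2
    planted_set_size: int | None = None

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.dna_depth < 0:
            raise ValueError("dna_depth must be >= 0")
        if self.barcodes_per_pair < 1:
            raise ValueError("barcodes_per_pair must be >= 1")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")


def _pair_keys(letters: Iterable[str]) -> list[str]:
    letters = sorted(set(letters))
    return sorted(
        {pair_key(a, b) for a, b in itertools.combinations_with_replacement(letters, 2)}
    )


def make_true_model(
    seed: int,
    alphabets: Mapping[str, str] | None = None,
    config: FeatureConfig | None = None,
) -> ScoringModel:
    """Random ground-truth model with standard-normal symmetric weights.

    Weights for every residue pair implied by the per-position
    alphabets are drawn i.i.d. from N(0, 1), as is the intercept.
    """
    alphabets = dict(alphabets or DEFAULT_ALPHABETS)
    config = config or FeatureConfig()
    rng = np.random.default_rng(seed)
    a_keys = _pair_keys(alphabets["a"])
    d_keys = _pair_keys(alphabets["d"])
    ge_keys = _pair_keys(set(alphabets["e"]) | set(alphabets["g"]))
    pair_weights = {
        "aa_core": {k: float(rng.normal()) for k in a_keys},
        "aa_nterm": {k: float(rng.normal()) for k in a_keys},
        "dd": {k: float(rng.normal()) for k in d_keys},
        "ge": {k: float(rng.normal()) for k in ge_keys},
    }
    consec = (
        {k: float(rng.normal()) for k in a_keys}
        if config.use_consecutive_a
        else None
    )
    return ScoringModel(
        pair_weights=pair_weights,
        consecutive_a_weights=consec,
        intercept=float(rng.normal()),
        config=config,
    )


def random_coils(
    n: int,
    seed: int,
    alphabets: Mapping[str, str] | None = None,
    n_heptads: int = 4,
    background: Background | None = None,
) -> list[CoiledCoil]:
    """Random distinct coils over per-position alphabets.

    Unlike :class:`~ccortho.ccgen.LibrarySpec` enumeration, the d
    position may vary here, which keeps the dd weight class
    identifiable in parameter-recovery fixtures.
    """
    alphabets = dict(alphabets or DEFAULT_ALPHABETS)
    background = background or Background()
    rng = np.random.default_rng(seed)
    bcf = background.per_heptad(n_heptads)
    seen: set[str] = set()
    coils: list[CoiledCoil] = []
    while len(coils) < n:
        chunks = []
        for j in range(n_heptads):
            b, c, f = bcf[j]
            a = alphabets["a"][rng.integers(len(alphabets["a"]))]
            d = alphabets["d"][rng.integers(len(alphabets["d"]))]
            e = alphabets["e"][rng.integers(len(alphabets["e"]))]
            g = alphabets["g"][rng.integers(len(alphabets["g"]))]
            chunks.append(a + b + c + d + e + f + g)
        residues = "".join(chunks)
        coil = CoiledCoil(
            id=f"syn{len(coils):04d}",
            residues=residues,
            n_heptads=n_heptads,
        )
        if coil.interfacial_signature in seen:
            continue
        seen.add(coil.interfacial_signature)
        coils.append(coil)
    return coils


def simulate_interactions(
    library: Sequence[CoiledCoil],
    model: ScoringModel,
    noise_sd: float,
    seed: int,
    n_pairs: int | None = None,
    shift_fraction: float = 0.0,
    on_target_pairs: Iterable[tuple[str, str]] = (),
) -> tuple[TrainingSet, pd.DataFrame]:
    """Noisy measured scores from a known model, with optional shifts.

    Each sampled pair's true score is its in-register score, except that
    a ``shift_fraction`` of off-target rows is instead scored at the
    best alignment under the true model (its true heptad offset is then
    whatever alignment wins).  Observed = true + N(0, noise_sd).
    Returns the training set and a truth table with the generating
    scores and offsets.
    """
    rng = np.random.default_rng(seed)
    by_id = {c.id: c for c in library}
    all_pairs = list(
        itertools.combinations_with_replacement(sorted(by_id), 2)
    )
    if n_pairs is not None:
        if n_pairs <= len(all_pairs):
            idx = rng.choice(len(all_pairs), size=n_pairs, replace=False)
        else:
            idx = rng.integers(0, len(all_pairs), size=n_pairs)
        pairs = [all_pairs[i] for i in sorted(idx)]
    else:
        pairs = all_pairs
    on_set = {tuple(sorted(p)) for p in on_target_pairs}
    truth_rows = []
    data_rows = []
    shifted_model = replace(
        model, config=replace(model.config, use_shifting=True)
    )
    for idA, idB in pairs:
        A, B = by_id[idA], by_id[idB]
        on_target = (idA, idB) in on_set
        shifted = (
            not on_target
            and shift_fraction > 0
            and rng.random() < shift_fraction
        )
        if shifted:
            true_score, true_offset = score_pair(A, B, shifted_model)
        else:
            aln0 = next(
                a
                for a in enumerate_alignments(A.n_heptads, B.n_heptads, 1)
                if a.offset_heptads == 0
            )
            true_score = score_alignment(A, B, aln0, model)
            true_offset = 0
        observed = true_score + rng.normal(0.0, noise_sd)
        data_rows.append(
            {"idA": idA, "idB": idB, "score": observed, "on_target": on_target}
        )
        truth_rows.append(
            {
                "idA": idA,
                "idB": idB,
                "true_score": true_score,
                "true_offset": true_offset,
                "shifted": shifted,
            }
        )
    ts = TrainingSet(pd.DataFrame(data_rows), by_id)
    return ts, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Barcode-level simulation

_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _random_barcodes(n: int, rng: np.random.Generator, length: int = 20):
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        bc = "".join(
            "ACGT"[i] for i in rng.integers(0, 4, size=length)
        )
        if bc in seen:
            continue
        seen.add(bc)
        out.append(bc)
    return out


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float):
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    p = dispersion / (dispersion + mean[pos])
    out[pos] = rng.negative_binomial(dispersion, p)
    return out


@dataclass
class SimulatedAssay:
    """Output bundle of :func:`simulate_barcode_data`."""

    rna: list[BarcodeCountTable]
    dna: list[BarcodeCountTable]
    barcode_map: BarcodeMap
    truth: pd.DataFrame  # idX, idY, score
    config: SynthConfig

    def fastq_records(self, kind: str, replicate: int):
        """Reads for one sample: each barcode emitted count times.

        Per-base substitution errors are applied at the configured rate;
        the stream is byte-deterministic for a fixed config seed.
        """
        tables = {"RNA": self.rna, "DNA": self.dna}[kind]
        table = tables[replicate]
        rng = np.random.default_rng(
            (self.config.seed, {"RNA": 1, "DNA": 2}[kind], replicate)
        )
        i = 0
        for bc in sorted(table.counts.index):
            count = int(table.counts[bc])
            base = np.frombuffer(bc.encode(), dtype="S1")
            for _ in range(count):
                read = base.copy()
                if self.config.error_rate > 0:
                    hits = rng.random(len(read)) < self.config.error_rate
                    if hits.any():
                        subs = rng.integers(0, 4, size=int(hits.sum()))
                        read[hits] = _BASES[subs]
                seq = read.tobytes().decode()
                rec = SeqRecord(
                    Seq(seq),
                    id=f"{kind}{replicate}_{i}",
                    description="",
                )
                rec.letter_annotations["phred_quality"] = [40] * len(seq)
                i += 1
                yield rec

    def write_fastq(self, path, kind: str, replicate: int) -> None:
        from Bio import SeqIO

        with open(path, "w") as fh:
            SeqIO.write(self.fastq_records(kind, replicate), fh, "fastq")


def simulate_barcode_data(
    interactions: pd.DataFrame, cfg: SynthConfig
) -> SimulatedAssay:
    """Barcode count tables realizing a table of planted pair scores.

    ``interactions`` needs columns ``idX``, ``idY``, ``score`` (finite).
    Every pair receives ``cfg.barcodes_per_pair`` distinct random
    barcodes; per replicate, DNA counts are NB(mean ``cfg.dna_depth``)
    and RNA counts NB(mean ``DNA x exp(score)``), both with dispersion
    ``cfg.rna_dispersion``.
    """
    required = {"idX", "idY", "score"}
    if not required <= set(interactions.columns):
        raise ValueError(f"interactions table needs columns {sorted(required)}")
    scores = interactions["score"].to_numpy(dtype=float)
    if not np.isfinite(scores).all():
        raise ValueError("planted interaction scores must be finite")
    rng = np.random.default_rng(cfg.seed)
    n_pairs = len(interactions)
    n_bc = n_pairs * cfg.barcodes_per_pair
    barcodes = _random_barcodes(n_bc, rng)
    map_rows = []
    bc_scores = np.repeat(scores, cfg.barcodes_per_pair)
    for i, r in enumerate(interactions.itertuples()):
        for b in range(cfg.barcodes_per_pair):
            map_rows.append(
                {
                    "barcode": barcodes[i * cfg.barcodes_per_pair + b],
                    "idX": r.idX,
                    "idY": r.idY,
                    "n_support": cfg.barcodes_per_pair,
                }
            )
    bmap = BarcodeMap(pd.DataFrame(map_rows))

    rna_tables = []
    dna_tables = []
    for rep in range(cfg.n_replicates):
        dna_counts = _nb_draw(
            rng, np.full(n_bc, cfg.dna_depth), cfg.rna_dispersion
        )
        rna_counts = _nb_draw(
            rng, dna_counts * np.exp(bc_scores), cfg.rna_dispersion
        )
        dna_tables.append(
            BarcodeCountTable(
                f"dna_rep{rep}",
                "DNA",
                rep,
                pd.Series(dna_counts, index=barcodes),
            )
        )
        rna_tables.append(
            BarcodeCountTable(
                f"rna_rep{rep}",
                "RNA",
                rep,
                pd.Series(rna_counts, index=barcodes),
            )
        )
    truth = interactions[["idX", "idY", "score"]].reset_index(drop=True)
    return SimulatedAssay(rna_tables, dna_tables, bmap, truth, cfg)


def plant_orthogonal_matrix(
    n_proteins: int,
    set_size: int,
    gap: float,
    noise_sd: float,
    seed: int,
) -> tuple[MeasuredMatrix, Pairing]:
    """Complete measured matrix with a planted orthogonal pairing.

    The planted pairing alternates homodimers and heterodimers.  Before
    noise, every planted on-target score exceeds every other
    interaction by at least ``gap + 4 * noise_sd``; independent
    N(0, noise_sd) noise is then added to both orientations of every
    measurement.
    """
    if n_proteins < 1 or set_size < 1:
        raise ValueError("n_proteins and set_size must be positive")
    rng = np.random.default_rng(seed)
    proteins = [f"P{i:02d}" for i in range(n_proteins)]
    pairs = []
    cursor = 0
    for k in range(set_size):
        if k % 2 == 0:
            if cursor + 1 > n_proteins:
                raise ValueError(
                    f"planting {set_size} pairs needs more than "
                    f"{n_proteins} proteins"
                )
            pairs.append((proteins[cursor], proteins[cursor]))
            cursor += 1
        else:
            if cursor + 2 > n_proteins:
                raise ValueError(
                    f"planting {set_size} pairs needs more than "
                    f"{n_proteins} proteins"
                )
            pairs.append((proteins[cursor], proteins[cursor + 1]))
            cursor += 2
    pairing = Pairing(pairs)
    on_set = set(pairing.pairs)

    margin = gap + 4.0 * noise_sd
    on_low, on_high = 5.0, 6.0
    off_high = on_low - margin
    off_width = min(gap / 2.0, 1.0) if gap > 0 else 1.0
    base = pd.DataFrame(0.0, index=proteins, columns=proteins)
    for i, j in itertools.combinations_with_replacement(proteins, 2):
        if (i, j) in on_set:
            v = float(rng.uniform(on_low, on_high))
        else:
            v = float(rng.uniform(off_high - off_width, off_high))
        base.at[i, j] = v
        base.at[j, i] = v
    rows = []
    for i in proteins:
        for j in proteins:
            rows.append(
                {
                    "idA": i,
                    "idB": j,
                    "score": base.at[i, j] + float(rng.normal(0.0, noise_sd)),
                }
            )
    return MeasuredMatrix(pd.DataFrame(rows)), pairing


def preset_cc0_like(seed: int = 7) -> dict:
    """A 16-protein all-against-all fixture (256 ordered interactions).

    Sixteen distinct coils from the default four-heptad a/e/g library
    are scored with a random ground-truth model; both orientations of
    every ordered pair receive independent measurement noise, and
    matching barcode-level count tables are generated.
    """
    cfg = SynthConfig(seed=seed)
    model = make_true_model(seed)
    coils = random_coils(16, seed)
    rng = np.random.default_rng(seed + 1)
    by_id = {c.id: c for c in coils}
    rows = []
    for idX in sorted(by_id):
        for idY in sorted(by_id):
            s, _ = score_pair(by_id[idX], by_id[idY], model)
            rows.append(
                {
                    "idX": idX,
                    "idY": idY,
                    "score": s + float(rng.normal(0.0, cfg.noise_sd)),
                }
            )
    interactions = pd.DataFrame(rows)
    assay = simulate_barcode_data(interactions, cfg)
    return {
        "config": cfg,
        "model": model,
        "coils": coils,
        "interactions": interactions,
        "assay": assay,
    }
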