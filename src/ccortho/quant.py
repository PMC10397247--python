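"""Barcode-sequencing quantification of protein-pair interactions.

In the underlying reporter assay every cloned protein pair carries one
or more unique 20-nt DNA barcodes; interacting pairs drive reporter
transcription, so the RNA abundance of a barcode relative to its DNA
(plasmid) abundance measures interaction strength.  The pipeline is:

1. extract the 20-bp barcode window from reads and count unique
   barcodes,
2. collapse sequencing errors by greedy Levenshtein clustering
   (distance <= 1 by default),
3. map barcodes to designed protein pairs by exact-match plurality
   voting,
4. keep barcodes with at least ``min_dna_reads`` in *every* DNA
   replicate, and summarize each pair as::

       interaction score = ln(median(RNA reads / DNA reads))

   over its retained barcodes.
"""
from __future__ import annotations

import gzip
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy import stats

__all__ = [
    "BarcodeCountTable",
    "BarcodeMap",
    "InteractionRecord",
    "QuantResult",
    "ReplicateAgreement",
    "extract_barcodes",
    "cluster_barcodes",
    "build_map",
    "interaction_scores",
    "replicate_agreement",
]

BARCODE_LEN = 20


@dataclass
class BarcodeCountTable:
    """Unique-barcode counts for one sequencing sample."""

    sample_id: str
    kind: str  # "RNA" | "DNA"
    replicate: int
    counts: pd.Series  # index: barcode, values: int counts
    dropped: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("RNA", "DNA"):
            raise ValueError(f"sample kind must be RNA or DNA, got {self.kind!r}")
        counts = pd.Series(self.counts, dtype=np.int64)
        if (counts < 0).any():
            raise ValueError("barcode counts must be non-negative")
        self.counts = counts

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_tsv(self, path) -> None:
        df = self.counts.rename("count").rename_axis("barcode").reset_index()
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, sample_id: str, kind: str, replicate: int = 0):
        df = pd.read_csv(path, sep="\t", dtype={"barcode": str})
        counts = pd.Series(
            df["count"].to_numpy(), index=df["barcode"].to_numpy()
        )
        return cls(sample_id, kind, replicate, counts)


def _open_maybe_gz(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def extract_barcodes(
    reads,
    offset: int,
    length: int = BARCODE_LEN,
    sample_id: str = "sample",
    kind: str = "DNA",
    replicate: int = 0,
) -> BarcodeCountTable:
    """Truncate reads to the barcode window and count unique sequences.

    ``reads`` is a FASTQ path (optionally gzipped), open handle, or an
    iterable of Bio.SeqRecord.  Reads shorter than ``offset + length``
    or containing ``N`` inside the window are dropped and tallied in the
    result's ``dropped`` dict.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    if isinstance(reads, (str, bytes)) or hasattr(reads, "__fspath__"):
        with _open_maybe_gz(reads) as fh:
            records = list(SeqIO.parse(fh, "fastq"))
    elif hasattr(reads, "read"):
        records = list(SeqIO.parse(reads, "fastq"))
    else:
        records = list(reads)
    counter: Counter[str] = Counter()
    dropped = {"too_short": 0, "ambiguous_base": 0}
    for rec in records:
        seq = str(rec.seq).upper()
        if len(seq) < offset + length:
            dropped["too_short"] += 1
            continue
        bc = seq[offset : offset + length]
        if set(bc) - set("ACGT"):
            dropped["ambiguous_base"] += 1
            continue
        counter[bc] += 1
    counts = pd.Series(counter, dtype=np.int64).sort_index()
    return BarcodeCountTable(sample_id, kind, replicate, counts, dropped)


def _within(bc1: str, bc2: str, max_dist: int) -> bool:
    res = edlib.align(bc1, bc2, mode="NW", task="distance", k=max_dist)
    return res["editDistance"] != -1


def cluster_barcodes(
    table: BarcodeCountTable, max_dist: int = 1
) -> BarcodeCountTable:
    """Collapse sequencing errors by greedy centroid clustering.

    Barcodes are visited in descending count order (ties lexicographic);
    each one merges into the first already-accepted centroid within
    Levenshtein distance ``max_dist``, otherwise it becomes a centroid
    itself.  Total read count is conserved exactly.
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if max_dist == 0 or len(table.counts) == 0:
        return BarcodeCountTable(
            table.sample_id,
            table.kind,
            table.replicate,
            table.counts.copy(),
            dict(table.dropped),
        )
    order = sorted(
        table.counts.items(), key=lambda kv: (-kv[1], kv[0])
    )
    centroids: list[str] = []
    merged: dict[str, int] = {}
    for bc, count in order:
        home = None
        for c in centroids:
            if _within(bc, c, max_dist):
                home = c
                break
        if home is None:
            centroids.append(bc)
            merged[bc] = int(count)
        else:
            merged[home] += int(count)
    counts = pd.Series(merged, dtype=np.int64).sort_index()
    return BarcodeCountTable(
        table.sample_id, table.kind, table.replicate, counts, dict(table.dropped)
    )


@dataclass
class BarcodeMap:
    """Barcode -> designed protein pair assignments with support counts.

    ``data`` columns: barcode, idX, idY, n_support.  Barcodes whose
    reads split ambiguously across designs are excluded upstream.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"barcode", "idX", "idY"}
        if not required <= set(self.data.columns):
            raise ValueError(f"barcode map needs columns {sorted(required)}")
        if self.data["barcode"].duplicated().any():
            raise ValueError("each barcode may map to only one protein pair")

    def __len__(self) -> int:
        return len(self.data)

    def lookup(self) -> dict[str, tuple[str, str]]:
        return {
            r.barcode: (r.idX, r.idY) for r in self.data.itertuples()
        }

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BarcodeMap":
        return cls(pd.read_csv(path, sep="\t", dtype={"barcode": str}))


def build_map(
    mapping_reads: Iterable[tuple[str, str]],
    reference: Mapping[str, tuple[str, str]],
    min_purity: float = 0.75,
) -> BarcodeMap:
    """Assign barcodes to designed pairs by exact-match plurality vote.

    ``mapping_reads`` yields (protein-region sequence, barcode) records
    from the mapping run; ``reference`` maps each designed pair's exact
    protein-region sequence to its (idX, idY).  Reads matching no design
    are ignored; a barcode is assigned only when its top-voted design
    collects at least ``min_purity`` of its design-matching reads,
    otherwise it is excluded as ambiguous.
    """
    if not reference:
        raise ValueError("reference design table is empty")
    votes: dict[str, Counter] = {}
    for seq, bc in mapping_reads:
        pair = reference.get(seq)
        if pair is None:
            continue
        votes.setdefault(bc, Counter())[pair] += 1
    rows = []
    for bc in sorted(votes):
        counter = votes[bc]
        total = sum(counter.values())
        (pair, top), = counter.most_common(1)
        if top / total >= min_purity:
            rows.append(
                {
                    "barcode": bc,
                    "idX": pair[0],
                    "idY": pair[1],
                    "n_support": top,
                }
            )
    return BarcodeMap(
        pd.DataFrame(rows, columns=["barcode", "idX", "idY", "n_support"])
    )


@dataclass(frozen=True)
class InteractionRecord:
    idX: str
    idY: str
    orientation: str
    interaction_score: float
    n_barcodes: int
    per_replicate: tuple[float, ...] = ()

    @property
    def flagged(self) -> bool:
        """True for -inf scores (all retained RNA counts were zero)."""
        return math.isinf(self.interaction_score)


@dataclass
class QuantResult:
    """Interaction records plus a tally of what the filters removed."""

    records: list[InteractionRecord]
    n_barcodes_retained: int = 0
    n_barcodes_filtered: int = 0
    pairs_dropped: list[tuple[str, str]] = field(default_factory=list)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "idX": r.idX,
                    "idY": r.idY,
                    "orientation": r.orientation,
                    "interaction_score": r.interaction_score,
                    "n_barcodes": r.n_barcodes,
                }
                for r in self.records
            ],
            columns=[
                "idX",
                "idY",
                "orientation",
                "interaction_score",
                "n_barcodes",
            ],
        )


def _aligned_counts(
    tables: Sequence[BarcodeCountTable], barcodes: pd.Index
) -> np.ndarray:
    """(n_replicates, n_barcodes) count array, missing barcodes as 0."""
    return np.stack(
        [
            t.counts.reindex(barcodes, fill_value=0).to_numpy()
            for t in tables
        ]
    )


def _ln_median(ratios: np.ndarray) -> float:
    med = float(np.median(ratios))
    if med <= 0.0:
        return -math.inf
    return math.log(med)


def interaction_scores(
    rna: Sequence[BarcodeCountTable],
    dna: Sequence[BarcodeCountTable],
    barcode_map: BarcodeMap,
    min_dna_reads: int = 10,
    pseudocount: float = 0.0,
    mode: str = "sum",
) -> QuantResult:
    """ln(median(RNA/DNA)) interaction scores per designed protein pair.

    A barcode is retained only if mapped and counted at least
    ``min_dna_reads`` times in every DNA replicate.  In ``mode="sum"``
    (default) counts are summed across replicates of each sample kind
    before forming one ratio per barcode; ``mode="per-replicate"`` pairs
    RNA and DNA replicates index-wise and takes the median over
    barcode x replicate ratios.  Pairs with no retained barcodes are
    omitted and tallied; an all-zero-RNA pair at pseudocount 0 gets a
    flagged ``-inf`` score rather than being dropped.
    """
    if not rna or not dna:
        raise ValueError("at least one RNA and one DNA table are required")
    if mode not in ("sum", "per-replicate"):
        raise ValueError("mode must be 'sum' or 'per-replicate'")
    if mode == "per-replicate" and len(rna) != len(dna):
        raise ValueError("per-replicate mode needs equal RNA/DNA replicates")
    lookup = barcode_map.lookup()
    barcodes = pd.Index(sorted(lookup))
    dna_counts = _aligned_counts(dna, barcodes)
    rna_counts = _aligned_counts(rna, barcodes)
    keep = (dna_counts >= min_dna_reads).all(axis=0)
    n_retained = int(keep.sum())

    by_pair: dict[tuple[str, str], list[int]] = {}
    for idx, bc in enumerate(barcodes):
        if keep[idx]:
            by_pair.setdefault(lookup[bc], []).append(idx)

    records = []
    pairs_dropped = sorted(set(lookup.values()) - set(by_pair))
    for (idX, idY), idxs in sorted(by_pair.items()):
        idxs = np.asarray(idxs)
        if mode == "sum":
            rna_tot = rna_counts[:, idxs].sum(axis=0)
            dna_tot = dna_counts[:, idxs].sum(axis=0)
            ratios = (rna_tot + pseudocount) / dna_tot
        else:
            ratios = (
                (rna_counts[:, idxs] + pseudocount) / dna_counts[:, idxs]
            ).ravel()
        per_rep = tuple(
            _ln_median((rna_counts[r, idxs] + pseudocount) / dna_counts[r, idxs])
            for r in range(min(len(rna), len(dna)))
        )
        records.append(
            InteractionRecord(
                idX=idX,
                idY=idY,
                orientation="XY",
                interaction_score=_ln_median(ratios),
                n_barcodes=len(idxs),
                per_replicate=per_rep,
            )
        )
    return QuantResult(
        records=records,
        n_barcodes_retained=n_retained,
        n_barcodes_filtered=len(barcodes) - n_retained,
        pairs_dropped=pairs_dropped,
    )


@dataclass(frozen=True)
class ReplicateAgreement:
    pearson_r: float
    n_shared: int
    max_abs_delta: float
    deltas: pd.Series

    @property
    def supports_gap(self) -> float:
        """Smallest orthogonality gap clearly exceeding replicate noise."""
        return self.max_abs_delta


def replicate_agreement(
    records_rep1: Iterable[InteractionRecord],
    records_rep2: Iterable[InteractionRecord],
    min_shared: int = 3,
) -> ReplicateAgreement:
    """Pearson correlation and score deltas between two replicate runs.

    The maximum absolute score delta summarizes measurement uncertainty
    and supports choosing an orthogonality-gap threshold safely above it.
    """
    s1 = {
        (r.idX, r.idY): r.interaction_score
        for r in records_rep1
        if math.isfinite(r.interaction_score)
    }
    s2 = {
        (r.idX, r.idY): r.interaction_score
        for r in records_rep2
        if math.isfinite(r.interaction_score)
    }
    shared = sorted(set(s1) & set(s2))
    if len(shared) < min_shared:
        raise ValueError(
            f"only {len(shared)} shared pairs between replicates "
            f"(need >= {min_shared})"
        )
    x = np.array([s1[p] for p in shared])
    y = np.array([s2[p] for p in shared])
    r, _ = stats.pearsonr(x, y)
    deltas = pd.Series(
        y - x, index=[f"{a}|{b}" for a, b in shared], name="delta"
    )
    return ReplicateAgreement(
        pearson_r=float(r),
        n_shared=len(shared),
        max_abs_delta=float(np.abs(y - x).max()),
        deltas=deltas,
    )
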