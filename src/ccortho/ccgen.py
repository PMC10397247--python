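"""Coiled-coil sequences on the heptad register.

A parallel dimeric coiled-coil is described by its heptad repeat
``abcdefg``: the ``a`` and ``d`` positions form the hydrophobic core of
the dimer interface, ``e`` and ``g`` flank it and form inter-helical
electrostatic contacts, and ``b``/``c``/``f`` face the solvent.  This
module represents register-annotated sequences, validates them,
enumerates combinatorial libraries that vary only the interfacial
``a``/``e``/``g`` positions on a fixed surface *background*, and reads
and writes such libraries as FASTA.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
REGISTER = "abcdefg"

__all__ = [
    "CANONICAL_AA",
    "REGISTER",
    "CoiledCoil",
    "Background",
    "LibrarySpec",
    "InvalidCoilError",
    "InvalidSpecError",
    "position_class",
    "interfacial_signature",
    "enumerate_library",
    "write_fasta",
    "read_fasta",
]


class InvalidCoilError(ValueError):
    """A sequence violates the heptad-register contract."""


class InvalidSpecError(ValueError):
    """A library specification is malformed (e.g. empty alphabet)."""


def _check_residues(residues: str, where: str) -> None:
    bad = set(residues) - CANONICAL_AA
    if bad:
        raise InvalidCoilError(
            f"{where}: non-canonical residue letter(s) {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class CoiledCoil:
    """A register-annotated amino-acid chain made of whole heptads.

    Parameters
    ----------
    id : str
        Unique identifier; library coils encode the interfacial residue
        string plus the background name.
    residues : str
        One-letter amino-acid sequence of length ``7 * n_heptads``.
    n_heptads : int
        Number of complete heptads.
    register_start : str
        Register letter of the first residue (default ``"a"``).  Partial
        heptads are rejected: the chain must contain whole heptads only.
    """

    id: str
    residues: str
    n_heptads: int
    register_start: str = "a"

    def __post_init__(self) -> None:
        if self.register_start not in REGISTER:
            raise InvalidCoilError(
                f"register_start must be one of {REGISTER!r}, "
                f"got {self.register_start!r}"
            )
        if self.n_heptads < 1:
            raise InvalidCoilError("n_heptads must be a positive integer")
        if len(self.residues) != 7 * self.n_heptads:
            raise InvalidCoilError(
                f"coil {self.id!r}: length {len(self.residues)} is not "
                f"7 x n_heptads = {7 * self.n_heptads}; partial heptads "
                "are rejected"
            )
        _check_residues(self.residues, f"coil {self.id!r}")

    def position_class(self, index: int) -> str:
        """Register letter (``a``..``g``) of residue ``index``."""
        if not 0 <= index < len(self.residues):
            raise IndexError(
                f"residue index {index} out of range for coil of length "
                f"{len(self.residues)}"
            )
        start = REGISTER.index(self.register_start)
        return REGISTER[(start + index) % 7]

    def residues_at(self, cls: str) -> str:
        """Residues occupying register position ``cls``, N- to C-terminal.

        Each register letter occurs exactly once per heptad, so the
        result has length ``n_heptads``; its ``j``-th character belongs
        to heptad ``j``.
        """
        if cls not in REGISTER:
            raise ValueError(f"unknown register position {cls!r}")
        start = REGISTER.index(self.register_start)
        first = (REGISTER.index(cls) - start) % 7
        return self.residues[first::7]

    def heptad(self, j: int) -> str:
        """The ``j``-th seven-residue block of the chain."""
        if not 0 <= j < self.n_heptads:
            raise IndexError(f"heptad index {j} out of range")
        return self.residues[7 * j : 7 * (j + 1)]

    @property
    def interfacial_signature(self) -> str:
        """Concatenated ``a``/``d``/``e``/``g`` residues per heptad.

        Two coils with the same signature present an identical dimer
        interface regardless of their surface background.
        """
        a = self.residues_at("a")
        d = self.residues_at("d")
        e = self.residues_at("e")
        g = self.residues_at("g")
        return "".join(
            a[j] + d[j] + e[j] + g[j] for j in range(self.n_heptads)
        )


def position_class(coil: CoiledCoil, index: int) -> str:
    """Register letter of residue ``index`` of ``coil``."""
    return coil.position_class(index)


def interfacial_signature(coil: CoiledCoil) -> str:
    """Interface identity string (a/d/e/g residues per heptad)."""
    return coil.interfacial_signature


@dataclass(frozen=True)
class Background:
    """Residues used at the solvent-facing b/c/f positions.

    Each of ``b_res``/``c_res``/``f_res`` is either a single letter
    (applied to every heptad) or a string of one letter per heptad.
    Backgrounds modulate helicity and solubility but leave the dimer
    interface — and hence pairing specificity — unchanged.
    """

    b_res: str = "A"
    c_res: str = "A"
    f_res: str = "A"
    name: str = "ala"

    def __post_init__(self) -> None:
        for res in (self.b_res, self.c_res, self.f_res):
            _check_residues(res, f"background {self.name!r}")
            if len(res) < 1:
                raise InvalidSpecError(
                    f"background {self.name!r}: empty residue field"
                )

    def _expand(self, res: str, n_heptads: int) -> str:
        if len(res) == 1:
            return res * n_heptads
        if len(res) != n_heptads:
            raise InvalidSpecError(
                f"background {self.name!r}: per-heptad residue string "
                f"{res!r} does not match n_heptads={n_heptads}"
            )
        return res

    def per_heptad(self, n_heptads: int) -> list[tuple[str, str, str]]:
        """(b, c, f) residues for each heptad."""
        b = self._expand(self.b_res, n_heptads)
        c = self._expand(self.c_res, n_heptads)
        f = self._expand(self.f_res, n_heptads)
        return [(b[j], c[j], f[j]) for j in range(n_heptads)]


def _check_alphabet(alpha: Sequence[str], name: str) -> tuple[str, ...]:
    letters = tuple(sorted(set(alpha)))
    if not letters:
        raise InvalidSpecError(f"{name} alphabet is empty")
    _check_residues("".join(letters), f"{name} alphabet")
    return letters


@dataclass(frozen=True)
class LibrarySpec:
    """Combinatorial coiled-coil library over a/e/g alphabets.

    Every heptad independently draws its ``a``, ``e`` and ``g`` residue
    from the respective alphabet; ``d`` is fixed to one residue and the
    surface positions come from ``background``.  The library therefore
    contains ``(|a| * |e| * |g|) ** n_heptads`` distinct coils.
    """

    n_heptads: int = 4
    a_alphabet: Sequence[str] = ("I", "N")
    e_alphabet: Sequence[str] = ("E", "K")
    g_alphabet: Sequence[str] = ("E", "K")
    d_res: str = "L"
    background: Background = field(default_factory=Background)

    def __post_init__(self) -> None:
        if self.n_heptads < 1:
            raise InvalidSpecError("n_heptads must be a positive integer")
        object.__setattr__(
            self, "a_alphabet", _check_alphabet(self.a_alphabet, "a")
        )
        object.__setattr__(
            self, "e_alphabet", _check_alphabet(self.e_alphabet, "e")
        )
        object.__setattr__(
            self, "g_alphabet", _check_alphabet(self.g_alphabet, "g")
        )
        if len(self.d_res) != 1:
            raise InvalidSpecError("d_res must be a single residue letter")
        _check_residues(self.d_res, "d residue")
        # fail early on per-heptad background length mismatches
        self.background.per_heptad(self.n_heptads)

    @property
    def size(self) -> int:
        """Closed-form library size ``(|a|*|e|*|g|) ** n_heptads``."""
        per = (
            len(self.a_alphabet) * len(self.e_alphabet) * len(self.g_alphabet)
        )
        return per**self.n_heptads


def enumerate_library(spec: LibrarySpec) -> list[CoiledCoil]:
    """Enumerate every coil of a combinatorial library.

    Returns coils in deterministic lexicographic order of their
    interfacial signature.  The default spec — four heptads with Ile/Asn
    at ``a`` and Glu/Lys at ``e`` and ``g`` — yields 4,096 coils.
    """
    bcf = spec.background.per_heptad(spec.n_heptads)
    per_heptad = list(
        itertools.product(spec.a_alphabet, spec.e_alphabet, spec.g_alphabet)
    )
    coils: list[CoiledCoil] = []
    for combo in itertools.product(per_heptad, repeat=spec.n_heptads):
        chunks = []
        sig_chunks = []
        for j, (a, e, g) in enumerate(combo):
            b, c, f = bcf[j]
            chunks.append(a + b + c + spec.d_res + e + f + g)
            sig_chunks.append(a + spec.d_res + e + g)
        sig = "".join(sig_chunks)
        coils.append(
            CoiledCoil(
                id=f"{sig}_{spec.background.name}",
                residues="".join(chunks),
                n_heptads=spec.n_heptads,
            )
        )
    assert len(coils) == spec.size
    return coils


# ---------------------------------------------------------------------------
# FASTA round-trip.  Header carries the register annotation:
#   >id register_start=a n_heptads=4 background=NAME

def write_fasta(coils: Iterable[CoiledCoil], path, background: str = "") -> None:
    """Write coils to FASTA with register metadata in the description."""
    records = []
    for coil in coils:
        bg = background or (coil.id.rsplit("_", 1)[1] if "_" in coil.id else "")
        desc = (
            f"register_start={coil.register_start} "
            f"n_heptads={coil.n_heptads} background={bg}"
        )
        records.append(
            SeqRecord(Seq(coil.residues), id=coil.id, description=desc)
        )
    SeqIO.write(records, path, "fasta")


def read_fasta(path) -> list[CoiledCoil]:
    """Read register-annotated coils written by :func:`write_fasta`."""
    coils = []
    for rec in SeqIO.parse(path, "fasta"):
        fields = dict(
            kv.split("=", 1)
            for kv in rec.description.split()
            if "=" in kv
        )
        seq = str(rec.seq)
        n_heptads = int(fields.get("n_heptads", len(seq) // 7))
        coils.append(
            CoiledCoil(
                id=rec.id,
                residues=seq,
                n_heptads=n_heptads,
                register_start=fields.get("register_start", "a"),
            )
        )
    return coils
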