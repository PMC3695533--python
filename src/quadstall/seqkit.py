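"""Sequence toolkit for the quadruplex-stalling analysis.

Covers the sequence-level plumbing the analysis needs: validated RNA/DNA
records, reverse complement, translation, synonymy checks between
quadruplex-forming-potential (QFP) sequence variants, a G-tract/loop QFP
scanner, nearest-neighbor extinction coefficients at 260 nm, and average
peptide masses for truncated translation products.

Coordinates are 0-based, half-open, always on the scanned strand; callers
reverse-complement explicitly when they need the other strand.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "NucleicSeq",
    "QfpHit",
    "PeptideMass",
    "SynonymyReport",
    "reverse_complement",
    "transcribe",
    "translate",
    "check_synonymy",
    "find_synonymous_frame",
    "scan_qfp",
    "scan_qfp_bruteforce",
    "extinction_coefficient",
    "peptide_mass",
    "read_fasta",
    "write_fasta",
    "load_qfp_primers",
    "load_hERalpha",
    "qfp_sense_windows",
    "VARIANTS",
]

VARIANTS = ("wild-type", "A-mutant", "C-mutant", "G-mutant", "U-mutant")

_DNA_BASES = frozenset("ACGT")
_RNA_BASES = frozenset("ACGU")

_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_RNA_COMPLEMENT = str.maketrans("ACGU", "UGCA")


@dataclass(frozen=True)
class NucleicSeq:
    """A validated single-stranded nucleic-acid sequence.

    Parameters
    ----------
    id : str
        Free-text label.
    residues : str
        Bases over ``{A, C, G, T}`` (DNA) or ``{A, C, G, U}`` (RNA).
        Case-insensitive on input; stored upper-case.
    alphabet : {"DNA", "RNA"}
        Must be consistent with the residues; T and U never mix.
    strand_note : str
        Free-text strand/provenance annotation (e.g. "antisense primer").
    """

    id: str
    residues: str
    alphabet: str
    strand_note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", self.residues.upper())
        if not self.residues:
            raise ValueError(f"{self.id!r}: empty sequence")
        if self.alphabet not in ("DNA", "RNA"):
            raise ValueError(f"{self.id!r}: alphabet must be DNA or RNA")
        allowed = _DNA_BASES if self.alphabet == "DNA" else _RNA_BASES
        for pos, base in enumerate(self.residues):
            if base not in allowed:
                raise ValueError(
                    f"{self.id!r}: invalid {self.alphabet} base {base!r} "
                    f"at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @classmethod
    def from_string(cls, residues: str, id: str = "seq",
                    strand_note: str = "") -> "NucleicSeq":
        """Build a record, inferring DNA vs RNA from T/U content.

        Sequences containing neither T nor U default to RNA (the study's
        oligos are RNA); a mix of T and U is rejected by validation.
        """
        upper = residues.upper()
        if "T" in upper and "U" in upper:
            raise ValueError(f"{id!r}: sequence mixes T and U")
        alphabet = "DNA" if "T" in upper else "RNA"
        return cls(id=id, residues=upper, alphabet=alphabet,
                   strand_note=strand_note)


@dataclass(frozen=True)
class QfpHit:
    """One quadruplex-forming-potential hit on the scanned strand.

    ``tracts`` holds ``(start, length)`` of each G-run; ``loop_lengths``
    the gaps between consecutive tracts. Coordinates 0-based, half-open.
    """

    start: int
    end: int
    tracts: tuple[tuple[int, int], ...]
    loop_lengths: tuple[int, ...]
    min_tract: int

    def __post_init__(self) -> None:
        if len(self.tracts) < 4:
            raise ValueError("a QFP hit needs at least 4 G-tracts")
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if any(length < self.min_tract for _, length in self.tracts):
            raise ValueError("tract shorter than min_tract")


@dataclass(frozen=True)
class PeptideMass:
    """Average mass of a peptide, optionally with one extra proton."""

    n_residues: int
    average_mass: float
    protonated_mass: float


@dataclass(frozen=True)
class SynonymyReport:
    """Per-variant codon comparison against a reference window."""

    variant_id: str
    n_codons_changed: int
    is_synonymous: bool


# ---------------------------------------------------------------------------
# basic strand operations


def reverse_complement(seq: NucleicSeq) -> NucleicSeq:
    """Watson-Crick complement in reverse order; alphabet preserved."""
    table = _DNA_COMPLEMENT if seq.alphabet == "DNA" else _RNA_COMPLEMENT
    return NucleicSeq(
        id=f"{seq.id}_rc",
        residues=seq.residues.translate(table)[::-1],
        alphabet=seq.alphabet,
        strand_note=f"reverse complement of {seq.id}",
    )


def transcribe(seq: NucleicSeq) -> NucleicSeq:
    """Coding-strand DNA -> RNA (T to U); RNA passes through unchanged."""
    if seq.alphabet == "RNA":
        return seq
    return NucleicSeq(
        id=seq.id,
        residues=seq.residues.replace("T", "U"),
        alphabet="RNA",
        strand_note=seq.strand_note,
    )


def translate(seq: NucleicSeq, frame: int = 0) -> str:
    """Translate with the standard genetic code.

    The trailing partial codon is dropped and stop codons render as ``*``.
    T and U are equivalent (the record's validation guarantees no
    ambiguity codes reach the codon table).
    """
    if frame not in (0, 1, 2):
        raise ValueError("frame must be 0, 1 or 2")
    coding = seq.residues[frame:]
    if len(coding) < 3:
        raise ValueError(
            f"{seq.id!r}: fewer than one codon at frame {frame}"
        )
    coding = coding[: len(coding) - len(coding) % 3]
    return str(Seq(coding).translate())


def check_synonymy(
    ref: NucleicSeq,
    variants: Sequence[NucleicSeq],
    frame: int = 0,
) -> list[SynonymyReport]:
    """Compare equal-length aligned windows codon-by-codon with ``ref``.

    A variant is synonymous iff its translation is identical to the
    reference translation; ``n_codons_changed`` counts codons that differ
    at the nucleotide level regardless of the encoded residue.
    """
    ref_aa = translate(ref, frame)
    ref_codons = _codons(ref.residues, frame)
    reports = []
    for var in variants:
        if len(var) != len(ref):
            raise ValueError(
                f"{var.id!r}: length {len(var)} != reference {len(ref)}"
            )
        var_codons = _codons(var.residues, frame)
        n_changed = sum(
            1 for a, b in zip(ref_codons, var_codons)
            if a.replace("T", "U") != b.replace("T", "U")
        )
        reports.append(
            SynonymyReport(
                variant_id=var.id,
                n_codons_changed=n_changed,
                is_synonymous=translate(var, frame) == ref_aa,
            )
        )
    return reports


def find_synonymous_frame(
    ref: NucleicSeq, variants: Sequence[NucleicSeq]
) -> int:
    """Return the reading frame in which every variant is synonymous.

    The printed QFP windows carry no frame annotation that a program can
    read, but only one frame renders all substitutions silent; try all
    three and return it.
    """
    for frame in (0, 1, 2):
        if all(r.is_synonymous for r in check_synonymy(ref, variants, frame)):
            return frame
    raise ValueError("no reading frame makes all variants synonymous")


def _codons(residues: str, frame: int) -> list[str]:
    coding = residues[frame:]
    return [coding[i: i + 3] for i in range(0, len(coding) - 2, 3)]


# ---------------------------------------------------------------------------
# QFP scanning


def _g_runs(residues: str, min_tract: int) -> list[tuple[int, int]]:
    """Maximal G-runs of length >= min_tract as (start, length)."""
    runs = []
    i = 0
    n = len(residues)
    while i < n:
        if residues[i] == "G":
            j = i
            while j < n and residues[j] == "G":
                j += 1
            if j - i >= min_tract:
                runs.append((i, j - i))
            i = j
        else:
            i += 1
    return runs


def scan_qfp(
    seq: NucleicSeq,
    min_tract: int = 2,
    loop_min: int = 1,
    loop_max: int = 7,
) -> list[QfpHit]:
    """Greedy left-to-right scan for >= 4 G-tracts with bounded loops.

    Tracts are maximal G-runs of length >= ``min_tract``; a hit chains
    consecutive qualifying runs whose gaps (loops) all lie within
    ``[loop_min, loop_max]``. Each hit is maximal (extends over as many
    chainable tracts as possible); scanning resumes after the reported
    end, so hits never overlap. Scans the given strand only.
    """
    if min_tract < 2:
        raise ValueError("min_tract must be >= 2")
    runs = _g_runs(seq.residues, min_tract)
    hits: list[QfpHit] = []
    i = 0
    while i < len(runs):
        # extend the chain from run i while loops stay in bounds
        j = i
        while j + 1 < len(runs):
            gap = runs[j + 1][0] - (runs[j][0] + runs[j][1])
            if loop_min <= gap <= loop_max:
                j += 1
            else:
                break
        if j - i + 1 >= 4:
            tracts = tuple(runs[i: j + 1])
            loops = tuple(
                tracts[k + 1][0] - (tracts[k][0] + tracts[k][1])
                for k in range(len(tracts) - 1)
            )
            hits.append(
                QfpHit(
                    start=tracts[0][0],
                    end=tracts[-1][0] + tracts[-1][1],
                    tracts=tracts,
                    loop_lengths=loops,
                    min_tract=min_tract,
                )
            )
            i = j + 1
        else:
            i += 1
    return hits


def scan_qfp_bruteforce(
    seq: NucleicSeq,
    min_tract: int = 2,
    loop_min: int = 1,
    loop_max: int = 7,
) -> list[QfpHit]:
    """Reference scanner: enumerate all run windows, then pick greedily.

    Independent of :func:`scan_qfp`'s chain-extension logic: every
    contiguous window of qualifying G-runs is enumerated with
    ``itertools.combinations`` of (first, last) indices, filtered on loop
    bounds, then selected leftmost-start / most-tracts without overlap.
    Used as an oracle in tests; quadratic in the number of runs.
    """
    runs = _g_runs(seq.residues, min_tract)
    candidates = []
    for a, b in itertools.combinations(range(len(runs) + 1), 2):
        window = runs[a:b]
        if len(window) < 4:
            continue
        gaps = [
            window[k + 1][0] - (window[k][0] + window[k][1])
            for k in range(len(window) - 1)
        ]
        if all(loop_min <= g <= loop_max for g in gaps):
            candidates.append((a, b, window, gaps))
    hits: list[QfpHit] = []
    blocked = -1  # last run index consumed
    for a, b, window, gaps in sorted(
        candidates, key=lambda c: (c[0], -(c[1] - c[0]))
    ):
        if a <= blocked:
            continue
        # maximality: skip if a longer candidate shares the same start
        if any(a2 == a and b2 > b for a2, b2, _, _ in candidates):
            continue
        hits.append(
            QfpHit(
                start=window[0][0],
                end=window[-1][0] + window[-1][1],
                tracts=tuple(window),
                loop_lengths=tuple(gaps),
                min_tract=min_tract,
            )
        )
        blocked = b - 1
    return hits


# ---------------------------------------------------------------------------
# extinction coefficients
#
# Nearest-neighbor molar extinction coefficients at 260 nm for RNA,
# 10^-3 L mol^-1 cm^-1, from Cantor, Warshaw & Shapiro (Biopolymers 1970),
# as tabulated in Puglisi & Tinoco, Methods Enzymol. 180 (1989). The table
# is module-level data so an alternative published table can be passed in.

EPSILON_MONO_RNA = {"A": 15340.0, "C": 7600.0, "G": 12160.0, "U": 10210.0}

EPSILON_NN_RNA = {
    "AA": 13650.0, "AC": 10670.0, "AG": 12790.0, "AU": 12140.0,
    "CA": 10670.0, "CC": 7520.0, "CG": 9390.0, "CU": 8370.0,
    "GA": 12920.0, "GC": 9190.0, "GG": 11430.0, "GU": 10960.0,
    "UA": 12520.0, "UC": 8900.0, "UG": 10400.0, "UU": 10110.0,
}


def extinction_coefficient(
    seq: NucleicSeq,
    mono_table: dict[str, float] = EPSILON_MONO_RNA,
    nn_table: dict[str, float] = EPSILON_NN_RNA,
) -> float:
    """Single-strand extinction coefficient at 260 nm, L mol^-1 cm^-1.

    Nearest-neighbor approximation::

        eps = sum_{i=1}^{n-1} 2*eps_NN(b_i b_{i+1})
            - sum_{i=2}^{n-1} eps_mono(b_i)

    A length-1 sequence returns the mononucleotide value. DNA input is
    converted T->U and evaluated against the RNA table (the study's
    oligos are RNA; the printed templates are their DNA antecedents).
    """
    residues = transcribe(seq).residues
    if len(residues) == 1:
        return mono_table[residues]
    nn_sum = sum(
        2.0 * nn_table[residues[i: i + 2]] for i in range(len(residues) - 1)
    )
    interior = sum(mono_table[b] for b in residues[1:-1])
    return nn_sum - interior


# ---------------------------------------------------------------------------
# peptide masses
#
# Average residue masses (Da), standard atomic weights; a free peptide adds
# one water, protonation adds one hydrogen atom. Average (not monoisotopic)
# masses match the MALDI-scale values quoted for the stalled products.

AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594,
    "N": 114.1038, "D": 115.0886, "Q": 128.1307, "K": 128.1741,
    "E": 129.1155, "M": 131.1926, "H": 137.1411, "F": 147.1766,
    "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}

WATER_AVERAGE_MASS = 18.0153
HYDROGEN_AVERAGE_MASS = 1.00794


def peptide_mass(aa_seq: str, protonated: bool = False) -> PeptideMass:
    """Average mass of a peptide from the standard 20 residues.

    ``protonated_mass`` always carries the +1 H value; the ``protonated``
    flag only selects which of the two is considered primary by callers
    (both fields are filled either way).
    """
    aa_seq = aa_seq.upper()
    if not aa_seq:
        raise ValueError("empty peptide")
    try:
        residue_sum = sum(AVERAGE_RESIDUE_MASS[a] for a in aa_seq)
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from None
    avg = residue_sum + WATER_AVERAGE_MASS
    return PeptideMass(
        n_residues=len(aa_seq),
        average_mass=avg,
        protonated_mass=avg + HYDROGEN_AVERAGE_MASS,
    )


# ---------------------------------------------------------------------------
# FASTA I/O and bundled study sequences


def read_fasta(path: str | Path) -> list[NucleicSeq]:
    """Read nucleic-acid records from a FASTA file."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            NucleicSeq.from_string(
                str(rec.seq), id=rec.id, strand_note=rec.description
            )
        )
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(seqs: Iterable[NucleicSeq], path: str | Path) -> None:
    """Write records to FASTA, preserving the stored alphabet."""
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=s.strand_note)
        for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")


def _data_path(name: str) -> Path:
    return Path(resources.files("quadstall").joinpath("data", name))


def load_qfp_primers() -> dict[str, NucleicSeq]:
    """The printed antisense primers and first-step template, by name.

    Keys: ``wild-type``, ``A-mutant``, ``C-mutant``, ``G-mutant``,
    ``U-mutant`` (69-nt antisense primers) and ``first-template``
    (49-nt template without the QFP insert). All DNA, antisense strand
    except the first template.
    """
    return {rec.id: rec for rec in read_fasta(_data_path("qfp_primers.fasta"))}


def load_hERalpha() -> str:
    """Canonical human estrogen receptor alpha protein sequence (595 aa)."""
    with open(_data_path("hERalpha.fasta")) as fh:
        lines = fh.read().splitlines()
    return "".join(line for line in lines if not line.startswith(">"))


def qfp_sense_windows(as_rna: bool = True) -> dict[str, NucleicSeq]:
    """Sense-strand QFP windows recovered from the antisense primers.

    Reverse-complements each printed 69-nt antisense primer; by default
    the windows are returned as RNA, matching the transcribed reporter.
    """
    primers = load_qfp_primers()
    windows = {}
    for name in VARIANTS:
        sense = reverse_complement(primers[name])
        if as_rna:
            sense = transcribe(sense)
        windows[name] = NucleicSeq(
            id=f"{name}_sense",
            residues=sense.residues,
            alphabet=sense.alphabet,
            strand_note=f"sense strand of {name} antisense primer",
        )
    return windows
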