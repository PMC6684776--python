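"""Cysteine-rich-peptide marker analytics.

Plant CRPs (defensins, hevein-like peptides, knottins, PA1b-like peptides)
are classified by their cysteine skeleton: the ordered spacing between
cysteines, written in C-Xn notation (e.g. ``C-X3-C-X7-C-X4-C-X-C-X9-C``).
This module extracts and renders those motifs, computes ungapped pairwise
identity between equal-length peptides, peptide masses (monoisotopic and
average) under free-thiol / disulfide-bonded / S-carbamidomethylated
cysteine states, and in-silico trypsin or chymotrypsin digests with missed
cleavages — the arithmetic used to match MALDI peaks to sequences.

Masses delegate to the standard residue-mass tables in ``pyteomics.mass``.

Coordinates in reports are 1-based inclusive (how residues are counted in
sequence annotation); internal indices are 0-based half-open.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyteomics import mass as _pmass

__all__ = [
    "PeptideSequence",
    "CysteineMotif",
    "DigestFragment",
    "cysteine_motif",
    "parse_motif",
    "cysteine_count",
    "pairwise_identity",
    "peptide_mass",
    "alkylation_shift",
    "digest",
    "read_fasta",
    "write_fasta",
]

_VALID = set("ACDEFGHIKLMNPQRSTVWY")

# Monoisotopic / average mass of a hydrogen atom (for disulfide arithmetic).
H_MONO = 1.00782503207
H_AVG = 1.00794
# Carbamidomethyl adduct on a free thiol (C2H3NO).
CAM_MONO = 57.02146
CAM_AVG = 57.0513
# Observed shift per cysteine when a fully disulfide-bonded peptide is
# reduced and S-alkylated: +H (reduction) + carbamidomethyl.
ALKYL_SHIFT_MONO = H_MONO + CAM_MONO   # 58.0293
ALKYL_SHIFT_NOMINAL = 58


@dataclass(frozen=True)
class PeptideSequence:
    """A named peptide over the 20 one-letter amino-acid codes."""

    name: str
    residues: str

    def __post_init__(self) -> None:
        seq = self.residues.strip().upper()
        object.__setattr__(self, "residues", seq)
        if not seq:
            raise ValueError("empty peptide sequence")
        bad = set(seq) - _VALID
        if bad:
            raise ValueError(f"invalid residue code(s) {sorted(bad)} in {self.name!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CysteineMotif:
    """Inter-cysteine spacing: gaps[i] residues between cysteines i and i+1."""

    gaps: tuple[int, ...]
    cysteine_count: int
    leading: int   # residues before the first cysteine
    trailing: int  # residues after the last cysteine

    def render(self) -> str:
        if self.cysteine_count == 0:
            return ""
        parts = ["C"]
        for g in self.gaps:
            if g == 0:
                parts.append("C")
            elif g == 1:
                parts.append("X-C")
            else:
                parts.append(f"X{g}-C")
        return "-".join(parts)


def cysteine_motif(p: PeptideSequence) -> CysteineMotif:
    """Extract the cysteine-spacing motif (empty for cysteine-free peptides)."""
    pos = [i for i, r in enumerate(p.residues) if r == "C"]
    if not pos:
        return CysteineMotif(gaps=(), cysteine_count=0, leading=len(p), trailing=0)
    gaps = tuple(pos[i + 1] - pos[i] - 1 for i in range(len(pos) - 1))
    return CysteineMotif(gaps=gaps, cysteine_count=len(pos),
                         leading=pos[0], trailing=len(p) - 1 - pos[-1])


def parse_motif(text: str) -> tuple[int, ...]:
    """Parse a C-Xn rendering back to its gap counts (round-trip of render)."""
    if text == "":
        return ()
    tokens = text.split("-")
    if tokens[0] != "C" or tokens[-1] != "C":
        raise ValueError(f"motif must start and end with C: {text!r}")
    gaps: list[int] = []
    i = 1
    while i < len(tokens):
        tok = tokens[i]
        if tok == "C":
            gaps.append(0)
            i += 1
        elif tok == "X":
            if i + 1 >= len(tokens) or tokens[i + 1] != "C":
                raise ValueError(f"malformed motif near {tok!r}")
            gaps.append(1)
            i += 2
        else:
            mt = re.fullmatch(r"X(\d+)", tok)
            if mt is None or i + 1 >= len(tokens) or tokens[i + 1] != "C":
                raise ValueError(f"malformed motif token {tok!r}")
            gaps.append(int(mt.group(1)))
            i += 2
    return tuple(gaps)


def cysteine_count(p: PeptideSequence) -> int:
    return p.residues.count("C")


def pairwise_identity(a: PeptideSequence, b: PeptideSequence) -> float:
    """Ungapped positional identity, percent to 1 decimal.

    Sequences must be equal length; for unequal lengths use an external
    aligner and compare the aligned columns instead.
    """
    if len(a) != len(b):
        raise ValueError(
            f"sequences differ in length ({len(a)} vs {len(b)}); "
            "align them externally before comparing"
        )
    matches = sum(x == y for x, y in zip(a.residues, b.residues))
    return round(100.0 * matches / len(a), 1)


def peptide_mass(p: PeptideSequence | str, kind: str = "mono",
                 cys_state: str | tuple[str, int] = "free") -> float:
    """Neutral peptide mass in Da.

    kind: ``"mono"`` (monoisotopic) or ``"average"``.
    cys_state:
      * ``"free"`` — reduced cysteines (free thiols);
      * ``("disulfide", n_bonds)`` — n_bonds S-S bridges, each removing two
        hydrogens (n_bonds <= floor(n_cys / 2));
      * ``"alkylated"`` — every cysteine S-carbamidomethylated (+57.02146
        mono per cysteine relative to the free-thiol form).
    """
    seq = p.residues if isinstance(p, PeptideSequence) else str(p)
    if kind not in ("mono", "average"):
        raise ValueError("kind must be 'mono' or 'average'")
    average = kind == "average"
    base = _pmass.calculate_mass(sequence=seq, average=average)
    n_cys = seq.count("C")
    h = H_AVG if average else H_MONO
    cam = CAM_AVG if average else CAM_MONO
    if cys_state == "free":
        return float(base)
    if cys_state == "alkylated":
        if n_cys == 0:
            raise ValueError("alkylated state requires at least one cysteine")
        return float(base + cam * n_cys)
    if isinstance(cys_state, tuple) and len(cys_state) == 2 and cys_state[0] == "disulfide":
        n_bonds = int(cys_state[1])
        if n_bonds < 0 or n_bonds > n_cys // 2:
            raise ValueError(f"{n_bonds} disulfide bonds impossible with {n_cys} cysteines")
        return float(base - 2.0 * h * n_bonds)
    raise ValueError(f"unknown cys_state {cys_state!r}")


def alkylation_shift(p: PeptideSequence, nominal: bool = True) -> float:
    """Mass increment from the fully disulfide-bonded peptide to its reduced,
    S-carbamidomethylated form: one hydrogen plus one carbamidomethyl group
    per cysteine (nominally 58 Da each)."""
    n_cys = cysteine_count(p)
    return float(ALKYL_SHIFT_NOMINAL * n_cys) if nominal else ALKYL_SHIFT_MONO * n_cys


@dataclass(frozen=True)
class DigestFragment:
    """One proteolytic fragment; span is 1-based inclusive on the parent."""

    start: int
    end: int
    residues: str
    missed_cleavages: int
    mass_mono: float
    mass_average: float


_ENZYME_SITES = {
    # cleave C-terminal to these residues, never before proline
    "trypsin": set("KR"),
    "chymotrypsin": set("FWY"),
    "chymotrypsin_low": set("FWYLM"),
}


def cleavage_positions(seq: str, enzyme: str) -> list[int]:
    """0-based positions i such that the bond after residue i is cut."""
    if enzyme not in _ENZYME_SITES:
        raise ValueError(f"unknown enzyme {enzyme!r}; choose from {sorted(_ENZYME_SITES)}")
    sites = _ENZYME_SITES[enzyme]
    cuts = []
    for i in range(len(seq) - 1):
        if seq[i] in sites and seq[i + 1] != "P":
            cuts.append(i)
    return cuts


def digest(p: PeptideSequence, enzyme: str = "trypsin",
           max_missed: int = 0) -> list[DigestFragment]:
    """In-silico digestion with 0..max_missed internal missed cleavages.

    Trypsin cuts C-terminal to K/R, chymotrypsin (high specificity)
    C-terminal to F/W/Y; neither cuts before proline.  Fragment masses are
    neutral, with free-thiol cysteines.  Fragments are ordered by start
    position then span length; the zero-missed fragments tile the parent.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be >= 0")
    seq = p.residues
    cuts = cleavage_positions(seq, enzyme)
    starts = [0] + [c + 1 for c in cuts]
    ends = [c + 1 for c in cuts] + [len(seq)]  # half-open piece boundaries
    out: list[DigestFragment] = []
    n_pieces = len(starts)
    for i in range(n_pieces):
        for m in range(min(max_missed, n_pieces - 1 - i) + 1):
            s, e = starts[i], ends[i + m]
            frag = seq[s:e]
            out.append(DigestFragment(
                start=s + 1, end=e, residues=frag, missed_cleavages=m,
                mass_mono=peptide_mass(frag, "mono"),
                mass_average=peptide_mass(frag, "average"),
            ))
    out.sort(key=lambda f: (f.start, f.end))
    return out


def read_fasta(path: str | Path) -> list[PeptideSequence]:
    """Read peptides from FASTA; names are the record ids, sequences
    uppercased with whitespace stripped."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    out = []
    for rec in records:
        seq = str(rec.seq).replace(" ", "").strip()
        if not seq:
            raise ValueError(f"empty FASTA record {rec.id!r}")
        out.append(PeptideSequence(name=rec.id, residues=seq))
    return out


def write_fasta(peptides, path: str | Path) -> None:
    records = [SeqRecord(Seq(p.residues), id=p.name, description="") for p in peptides]
    SeqIO.write(records, str(path), "fasta")
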