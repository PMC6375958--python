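"""Polybasic membrane-interaction motif scanning and composition grouping.

The conserved Raf-family membrane-interacting consensus is a fixed-length
pattern over one-letter amino-acid codes: an arginine, any residue, a
glutamate, four arbitrary residues, then the basic R(K)-K(R)-T-R block.  In
cRaf this matches R391 plus the 398-RKTR cluster on the aC-helix.  Two
presets ship: the strict consensus ``R x E x{4} [RK] [KR] T R`` (default)
and a relaxed variant ``[RK] x E x{4} [RK] [KR] [TLQ] R`` admitting the
wider substitutions seen across Raf-like kinases.

Membrane-interacting residue sets from known membrane-binding domains fall
into three composition groups: (1) largely positively charged, (2) positive
plus aromatic/hydrophobic, (3) polar/aromatic/hydrophobic with little or no
charge.  ``classify`` reproduces that grouping from residue-class fractions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

BASIC = set("RKH")
AROMATIC = set("FWY")
HYDROPHOBIC = set("AVLIMP")

#: Preset patterns (element syntax: letter, [set], x, x{n}).
RAF_STRICT = "R x E x{4} [RK] [KR] T R"
RAF_RELAXED = "[RK] x E x{4} [RK] [KR] [TLQ] R"
PRESETS = {"raf-strict": RAF_STRICT, "raf-relaxed": RAF_RELAXED}


@dataclass(frozen=True)
class MotifPattern:
    """A fixed-length motif: one allowed-residue set per position
    (``None`` = wildcard)."""

    name: str
    elements: tuple[frozenset[str] | None, ...]

    def __len__(self) -> int:
        return len(self.elements)

    @classmethod
    def parse(cls, text: str, name: str = "custom") -> "MotifPattern":
        """Parse whitespace-separated elements: ``A`` (fixed), ``[ABC]``
        (alternatives), ``x`` (wildcard), ``x{n}`` (n wildcards)."""
        elements: list[frozenset[str] | None] = []
        for tok in text.split():
            m = re.fullmatch(r"x\{(\d+)\}", tok)
            if m:
                elements.extend([None] * int(m.group(1)))
            elif tok == "x":
                elements.append(None)
            elif re.fullmatch(r"\[[A-Z]+\]", tok):
                aas = set(tok[1:-1])
                bad = aas - STANDARD_AA
                if bad:
                    raise ValueError(f"non-standard residues {sorted(bad)} in {tok}")
                elements.append(frozenset(aas))
            elif len(tok) == 1 and tok in STANDARD_AA:
                elements.append(frozenset(tok))
            else:
                raise ValueError(f"cannot parse pattern element {tok!r}")
        if not elements:
            raise ValueError("empty pattern")
        return cls(name=name, elements=tuple(elements))

    def matches_at(self, sequence: str, i: int) -> bool:
        if i + len(self.elements) > len(sequence):
            return False
        return all(e is None or sequence[i + j] in e
                   for j, e in enumerate(self.elements))


@dataclass(frozen=True)
class MotifMatch:
    """One motif occurrence, in caller-supplied numbering
    (position = offset + 1-based sequence index)."""

    seq_id: str
    start: int
    end: int
    matched: str


def scan(sequence: str, pattern: MotifPattern | str = RAF_STRICT,
         numbering_offset: int = 0, seq_id: str = "seq") -> list[MotifMatch]:
    """All (possibly overlapping) motif matches, left to right.

    ``numbering_offset`` maps sequence positions into author numbering:
    a match starting at 1-based index i is reported at ``offset + i``.  So a
    segment whose first residue is numbered 390 uses offset 389.
    """
    if isinstance(pattern, str):
        pattern = PRESETS.get(pattern) or pattern
        if isinstance(pattern, str):
            pattern = MotifPattern.parse(pattern)
    sequence = sequence.strip().upper()
    for pos, aa in enumerate(sequence):
        if aa not in STANDARD_AA:
            raise ValueError(
                f"non-standard residue {aa!r} at position {pos + 1}")
    L = len(pattern)
    out = []
    for i in range(len(sequence) - L + 1):
        if pattern.matches_at(sequence, i):
            out.append(MotifMatch(
                seq_id=seq_id,
                start=numbering_offset + i + 1,
                end=numbering_offset + i + L,
                matched=sequence[i:i + L],
            ))
    return out


def scan_fasta(path: str, pattern: MotifPattern | str = RAF_STRICT,
               numbering_offset: int = 0) -> list[MotifMatch]:
    """Scan every record of a FASTA file."""
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        out.extend(scan(str(rec.seq), pattern, numbering_offset,
                        seq_id=rec.id))
    return out


@dataclass(frozen=True)
class ResidueClassification:
    """Composition fractions of a membrane-interacting residue set and its
    assigned group (1: largely basic; 2: basic + aromatic/hydrophobic;
    3: polar/aromatic/hydrophobic)."""

    residues: tuple[str, ...]
    basic_fraction: float
    aromatic_fraction: float
    hydrophobic_fraction: float
    polar_other_fraction: float
    group: int


def classify(residues, basic_threshold: float = 0.6,
             apolar_threshold: float = 0.25) -> ResidueClassification:
    """Assign a membrane-interacting residue multiset to a composition group.

    Group 1 when the basic fraction reaches ``basic_threshold`` and the
    aromatic+hydrophobic fraction stays below ``apolar_threshold``; group 2
    when basic >= ``apolar_threshold`` alongside substantial
    aromatic/hydrophobic content; otherwise group 3.  Histidine counts as
    basic.  The thresholds are this package's calibration of a grouping the
    source classification gives by example.
    """
    residues = tuple(str(r).upper() for r in residues)
    if not residues:
        raise ValueError("empty residue set")
    bad = [r for r in residues if r not in STANDARD_AA]
    if bad:
        raise ValueError(f"unknown residue codes {bad}")
    n = len(residues)
    f_basic = sum(r in BASIC for r in residues) / n
    f_arom = sum(r in AROMATIC for r in residues) / n
    f_hyd = sum(r in HYDROPHOBIC for r in residues) / n
    f_other = 1.0 - f_basic - f_arom - f_hyd
    apolar = f_arom + f_hyd
    if f_basic >= basic_threshold and apolar < apolar_threshold:
        group = 1
    elif f_basic >= apolar_threshold and apolar >= apolar_threshold:
        group = 2
    else:
        group = 3
    return ResidueClassification(residues, f_basic, f_arom, f_hyd,
                                 f_other, group)


def interface_code(residues: list[tuple[int, str]],
                   elements: list[str] | None = None) -> str:
    """Render an ordered membrane-interacting residue set as a compact
    surface code, e.g. ``YYW..R.RKTR..RN.RW``.

    ``residues`` is a list of (residue_number, one_letter) sorted (or
    sortable) by number.  Without ``elements``, separators encode gap size:
    adjacent residues concatenate, a gap of one residue renders ``.``, and
    larger gaps render ``..``.  With ``elements`` (one structural-element
    label per residue, e.g. the secondary-structure element it comes from),
    separators follow the membrane-binding-domain convention instead: a
    ``.`` separates non-adjacent residues of the same element and ``..``
    marks an element change.
    """
    if not residues:
        raise ValueError("empty residue list")
    order = sorted(range(len(residues)), key=lambda i: residues[i][0])
    residues = [residues[i] for i in order]
    if elements is not None:
        if len(elements) != len(residues):
            raise ValueError("elements must match residues one-to-one")
        elements = [elements[i] for i in order]
    numbers = [n for n, _ in residues]
    if len(set(numbers)) != len(numbers):
        raise ValueError("duplicate residue numbers")
    for _, aa in residues:
        if aa.upper() not in STANDARD_AA:
            raise ValueError(f"unknown residue code {aa!r}")

    out = [residues[0][1].upper()]
    for i in range(1, len(residues)):
        gap = numbers[i] - numbers[i - 1] - 1
        if elements is not None:
            if elements[i] != elements[i - 1]:
                sep = ".."
            elif gap == 0:
                sep = ""
            else:
                sep = "."
        else:
            sep = "" if gap == 0 else ("." if gap == 1 else "..")
        out.append(sep + residues[i][1].upper())
    return "".join(out)
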