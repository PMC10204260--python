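"""Core domain types for clinical CNV reinterpretation.

Coordinates follow the ISCN convention throughout the package: 1-based,
inclusive on both ends, so ``length = end - start + 1``.  BED and chain-file
I/O convert to/from 0-based half-open at the boundary.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

__all__ = [
    "Assembly",
    "GenomicInterval",
    "CopyState",
    "Inheritance",
    "Classification",
    "CNVType",
    "Sex",
    "TestContext",
    "CNVCall",
    "ClassChange",
    "ISCNRecord",
    "ISCNParseError",
    "ValidationError",
    "AssemblyMismatchError",
    "AmbiguousTypeError",
    "NoCopyChangeError",
    "SexRequiredError",
    "parse_iscn",
    "parse_iscn_one",
    "format_iscn",
    "FormattedISCN",
    "infer_type",
    "reciprocal_overlap",
    "CHROMOSOMES",
]


class ValidationError(ValueError):
    """An object violates a domain invariant."""


class AssemblyMismatchError(ValidationError):
    """Two coordinate-bearing objects are on different genome builds.

    Run liftover first; no silent conversion is performed.
    """


class ISCNParseError(ValueError):
    def __init__(self, message: str, token: str = "", position: int = -1):
        self.token = token
        self.position = position
        if token:
            message = f"{message} (token {token!r} at position {position})"
        super().__init__(message)


class AmbiguousTypeError(ValidationError):
    """Copy state straddles (or equals) expected ploidy; an explicit label is needed."""


class NoCopyChangeError(ValidationError):
    """Copy state equals expected ploidy — not a CNV."""


class SexRequiredError(ValidationError):
    """Sex-chromosome copy state cannot be typed without patient sex or a label."""


class Assembly(str, enum.Enum):
    """Genome build. The study era spans NCBI36/hg18 (until 2011) and GRCh37/hg19."""

    HG18 = "hg18"
    HG19 = "hg19"
    UNSPECIFIED = "unspecified"

    @classmethod
    def from_tag(cls, tag: str) -> "Assembly":
        t = tag.strip().lower().lstrip("[").rstrip("]")
        aliases = {
            "hg18": cls.HG18,
            "ncbi36": cls.HG18,
            "ncbi36/hg18": cls.HG18,
            "hg19": cls.HG19,
            "grch37": cls.HG19,
            "grch37/hg19": cls.HG19,
            "unspecified": cls.UNSPECIFIED,
            "": cls.UNSPECIFIED,
        }
        if t not in aliases:
            raise ISCNParseError(f"unknown genome build tag {tag!r}")
        return aliases[t]


CHROMOSOMES: tuple = tuple(str(i) for i in range(1, 23)) + ("X", "Y")


def normalize_chrom(chrom) -> str:
    c = str(chrom).strip()
    if c.lower().startswith("chr"):
        c = c[3:]
    c = c.upper() if c.upper() in ("X", "Y") else c
    if c not in CHROMOSOMES:
        raise ValidationError(f"invalid chromosome {chrom!r}")
    return c


def _compatible(a: Assembly, b: Assembly) -> bool:
    # UNSPECIFIED acts as a wildcard on comparison.
    return a == b or Assembly.UNSPECIFIED in (a, b)


@dataclass(frozen=True)
class GenomicInterval:
    """1-based inclusive genomic interval on a single chromosome."""

    chrom: str
    start: int
    end: int
    assembly: Assembly = Assembly.UNSPECIFIED

    def __post_init__(self):
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if not isinstance(self.assembly, Assembly):
            object.__setattr__(self, "assembly", Assembly(self.assembly))
        if not (1 <= self.start <= self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 1 <= start <= end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def overlap_bases(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """min(overlap/len(a), overlap/len(b)); the field's 'same CNV' criterion.

    Raises :class:`AssemblyMismatchError` when the two intervals are on
    different (specified) builds.
    """
    if not _compatible(a.assembly, b.assembly):
        raise AssemblyMismatchError(
            f"intervals on {a.assembly.value} vs {b.assembly.value}; liftover first"
        )
    ov = a.overlap_bases(b)
    if ov == 0:
        return 0.0
    return min(ov / a.length, ov / b.length)


@dataclass(frozen=True)
class CopyState:
    """Integer copy-number range; low == high for non-mosaic states.

    A mixed state such as x2~3 (duplication-triplication) has low=2, high=3.
    """

    low: int
    high: int

    def __post_init__(self):
        if self.low < 0 or self.high < self.low:
            raise ValidationError(f"invalid copy state x{self.low}~{self.high}")

    @property
    def mosaic(self) -> bool:
        return self.low != self.high

    def __str__(self) -> str:
        return f"x{self.low}" if not self.mosaic else f"x{self.low}~{self.high}"


class Inheritance(str, enum.Enum):
    DE_NOVO = "de_novo"
    MATERNAL = "maternal"
    PATERNAL = "paternal"
    # "non_maternal": not inherited from the mother, father unavailable for testing.
    NON_MATERNAL = "non_maternal"
    NON_PATERNAL = "non_paternal"
    INHERITED_UNSPECIFIED = "inherited_unspecified"
    UNKNOWN = "unknown"

    @property
    def is_inherited(self) -> bool:
        return self in (
            Inheritance.MATERNAL,
            Inheritance.PATERNAL,
            Inheritance.INHERITED_UNSPECIFIED,
        )


class Classification(enum.IntEnum):
    """Five-tier classification with the total order used for up/downgrades:
    benign < likely_benign < uncertain < likely_pathogenic < pathogenic.
    """

    BENIGN = 0
    LIKELY_BENIGN = 1
    UNCERTAIN = 2
    LIKELY_PATHOGENIC = 3
    PATHOGENIC = 4

    @property
    def label(self) -> str:
        return _CLASS_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Classification":
        key = label.strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return _CLASS_FROM_LABEL[key]
        except KeyError:
            raise ValidationError(f"unknown classification {label!r}") from None


_CLASS_LABELS = {
    Classification.BENIGN: "benign",
    Classification.LIKELY_BENIGN: "likely_benign",
    Classification.UNCERTAIN: "uncertain",
    Classification.LIKELY_PATHOGENIC: "likely_pathogenic",
    Classification.PATHOGENIC: "pathogenic",
}
_CLASS_FROM_LABEL = {
    "benign": Classification.BENIGN,
    "b": Classification.BENIGN,
    "likely_benign": Classification.LIKELY_BENIGN,
    "lb": Classification.LIKELY_BENIGN,
    "uncertain": Classification.UNCERTAIN,
    "vus": Classification.UNCERTAIN,
    "uncertain_significance": Classification.UNCERTAIN,
    "likely_pathogenic": Classification.LIKELY_PATHOGENIC,
    "lp": Classification.LIKELY_PATHOGENIC,
    "pathogenic": Classification.PATHOGENIC,
    "p": Classification.PATHOGENIC,
}


class CNVType(str, enum.Enum):
    LOSS = "loss"
    GAIN = "gain"


class Sex(str, enum.Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


class TestContext(str, enum.Enum):
    PRENATAL = "prenatal"
    POSTNATAL = "postnatal"


def expected_ploidy(chrom: str, sex: Sex) -> Optional[int]:
    """Expected copy number for a chromosome given patient sex; None if sex needed."""
    chrom = normalize_chrom(chrom)
    if chrom == "X":
        return {Sex.F: 2, Sex.M: 1}.get(sex)
    if chrom == "Y":
        return {Sex.F: 0, Sex.M: 1}.get(sex)
    return 2


def infer_type(
    copy_state: CopyState,
    chrom: str,
    patient_sex: Sex = Sex.UNKNOWN,
    label: Optional[CNVType] = None,
) -> CNVType:
    """Derive loss/gain from a copy state relative to expected ploidy.

    loss iff high < expected, gain iff low > expected.  On sex chromosomes
    (where the comparator's sex drives the array ratio) an explicit ``label``
    resolves states the ploidy arithmetic cannot, e.g. x2 on chrX in a
    female; on autosomes a non-mosaic state equal to ploidy is never a CNV.
    """
    chrom = normalize_chrom(chrom)
    sex_chrom = chrom in ("X", "Y")
    exp = expected_ploidy(chrom, patient_sex)
    if exp is None:
        if label is not None:
            return label
        raise SexRequiredError(
            f"copy state {copy_state} on chr{chrom} requires patient sex or a type label"
        )
    if copy_state.high < exp:
        return CNVType.LOSS
    if copy_state.low > exp:
        return CNVType.GAIN
    if copy_state.low == copy_state.high == exp:
        if sex_chrom and label is not None:
            return label
        raise NoCopyChangeError(
            f"copy state {copy_state} equals expected ploidy {exp} on chr{chrom}: no copy change"
        )
    # Mosaic range straddling or touching expected ploidy (e.g. x2~3 with ploidy 2).
    if label is not None:
        return label
    raise AmbiguousTypeError(
        f"copy state {copy_state} is ambiguous against ploidy {exp} on chr{chrom}; "
        "provide an explicit loss/gain label"
    )


@dataclass
class CNVCall:
    """One observed CNV with coordinates, copy state and patient/test metadata."""

    id: str
    interval: GenomicInterval
    band: str
    copy_state: CopyState
    inheritance: Inheritance = Inheritance.UNKNOWN
    patient_id: str = ""
    patient_sex: Sex = Sex.UNKNOWN
    test_year: int = 0
    context: TestContext = TestContext.POSTNATAL
    initial_class: Classification = Classification.UNCERTAIN
    final_class: Optional[Classification] = None
    phenotype: tuple = ()
    type_label: Optional[CNVType] = None
    # Affected status of the transmitting parent, when clinically assessed;
    # None (the default) means unknown and contributes no benign evidence.
    parent_affected: Optional[bool] = None

    @property
    def cnv_type(self) -> CNVType:
        return infer_type(
            self.copy_state, self.interval.chrom, self.patient_sex, self.type_label
        )

    @property
    def length(self) -> int:
        return self.interval.length

    def with_final(self, cls: Classification) -> "CNVCall":
        return replace(self, final_class=cls)


class ChangeDirection(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    NONE = "none"


@dataclass(frozen=True)
class ClassChange:
    cnv_id: str
    from_class: Classification
    to_class: Classification

    @property
    def direction(self) -> ChangeDirection:
        if self.to_class > self.from_class:
            return ChangeDirection.UP
        if self.to_class < self.from_class:
            return ChangeDirection.DOWN
        return ChangeDirection.NONE


# ---------------------------------------------------------------------------
# ISCN-style array notation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ISCNRecord:
    """One locus parsed from array-CNV ISCN notation."""

    chrom: str
    band: str  # may be "" for the chrN:(start-end) style
    start: int
    end: int
    copy_state: CopyState
    assembly: Assembly = Assembly.UNSPECIFIED
    inheritance: Optional[Inheritance] = None

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.assembly)


_ASSEMBLY_TAG_RE = re.compile(r"\[\s*(?P<tag>[A-Za-z0-9/]+)\s*\]")
_BAND_LOCUS_RE = re.compile(
    r"(?P<chrom>2[0-2]|1[0-9]|[1-9]|[XY])"
    r"(?P<band>[pq][0-9]+(?:\.[0-9]+)?(?:[pq][0-9]+(?:\.[0-9]+)?)?)"
    r"\(\s*(?P<start>\d+)\s*[-_]\s*(?P<end>\d+)\s*\)"
    r"x(?P<low>\d+)(?:~(?P<high>\d+))?",
    re.IGNORECASE,
)
_CHR_LOCUS_RE = re.compile(
    r"chr(?P<chrom>2[0-2]|1[0-9]|[1-9]|[XY])\s*:?\s*"
    r"\(\s*(?P<start>\d+)\s*[-_]\s*(?P<end>\d+)\s*\)"
    r"x(?P<low>\d+)(?:~(?P<high>\d+))?",
    re.IGNORECASE,
)
_TRAILING_INHERITANCE = {
    "dn": Inheritance.DE_NOVO,
    "denovo": Inheritance.DE_NOVO,
    "mat": Inheritance.MATERNAL,
    "pat": Inheritance.PATERNAL,
    "inh": Inheritance.INHERITED_UNSPECIFIED,
}


def parse_iscn(text: str) -> list[ISCNRecord]:
    """Parse array-CNV ISCN notation into one record per locus.

    Grammar: optional ``arr`` prefix, optional ``[hgNN]`` build tag, then one
    or more loci separated by commas/whitespace.  A locus is either
    ``<chrom><band>(<start>-<end>)x<n>[~<m>]`` or the colon style
    ``chr<chrom>:(<start>-<end>)x<n>[~<m>]``; ``-`` and ``_`` both separate
    coordinates.  Trailing ``dn``/``mat``/``pat``/``inh`` tokens set the
    inheritance of the preceding locus.
    """
    s = text.strip()
    if not s:
        raise ISCNParseError("empty ISCN string")
    pos = 0
    assembly = Assembly.UNSPECIFIED
    m = re.match(r"\s*arr\b", s[pos:], re.IGNORECASE)
    if m:
        pos += m.end()
    m = re.match(r"\s*" + _ASSEMBLY_TAG_RE.pattern, s[pos:])
    if m:
        assembly = Assembly.from_tag(m.group("tag"))
        pos += m.end()

    records: list[ISCNRecord] = []
    while pos < len(s):
        m = re.match(r"[\s,;]+", s[pos:])
        if m:
            pos += m.end()
        if pos >= len(s):
            break
        m = _BAND_LOCUS_RE.match(s, pos) or _CHR_LOCUS_RE.match(s, pos)
        if m is None:
            # Trailing inheritance token applying to the previous locus?
            tok_m = re.match(r"\S+", s[pos:])
            tok = tok_m.group(0) if tok_m else s[pos:]
            key = tok.lower().rstrip(".")
            if records and key in _TRAILING_INHERITANCE:
                records[-1] = replace(
                    records[-1], inheritance=_TRAILING_INHERITANCE[key]
                )
                pos += tok_m.end()
                continue
            raise ISCNParseError("malformed ISCN locus", token=tok, position=pos)
        g = m.groupdict()
        start, end = int(g["start"]), int(g["end"])
        if start > end:
            raise ValidationError(
                f"start {start} > end {end} in ISCN locus {m.group(0)!r}"
            )
        low = int(g["low"])
        high = int(g["high"]) if g.get("high") else low
        records.append(
            ISCNRecord(
                chrom=normalize_chrom(g["chrom"]),
                band=g.get("band") or "",
                start=start,
                end=end,
                copy_state=CopyState(low, high),
                assembly=assembly,
            )
        )
        pos = m.end()
    if not records:
        raise ISCNParseError("no locus found", token=s, position=0)
    return records


def parse_iscn_one(text: str) -> ISCNRecord:
    """Parse notation expected to contain exactly one locus."""
    recs = parse_iscn(text)
    if len(recs) != 1:
        raise ISCNParseError(f"expected one locus, found {len(recs)}")
    return recs[0]


class FormattedISCN(str):
    """An ISCN string with formatting metadata attached."""

    coordinate_only: bool = False


def format_iscn(record, style: str = "bare") -> FormattedISCN:
    """Canonical ISCN rendering: ``<chrom><band>(<start>-<end>)x<n>[~<m>]``.

    ``style='with_arr_prefix'`` prepends ``arr [hgNN] `` when the assembly is
    known.  A record without a band falls back to the coordinate-only
    ``chr<chrom>:(...)`` form, flagged via ``.coordinate_only`` on the result.
    """
    if isinstance(record, CNVCall):
        chrom = record.interval.chrom
        band = record.band or ""
        start, end = record.interval.start, record.interval.end
        cs = record.copy_state
        assembly = record.interval.assembly
    else:
        chrom, band = record.chrom, record.band
        start, end = record.start, record.end
        cs = record.copy_state
        assembly = record.assembly

    coordinate_only = not band
    if coordinate_only:
        body = f"chr{chrom}:({start}-{end}){cs}"
    else:
        body = f"{chrom}{band}({start}-{end}){cs}"
    if style == "with_arr_prefix":
        tag = f"[{assembly.value}] " if assembly != Assembly.UNSPECIFIED else ""
        body = f"arr {tag}{body}"
    elif style != "bare":
        raise ValueError(f"unknown style {style!r}")
    out = FormattedISCN(body)
    out.coordinate_only = coordinate_only
    return out
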