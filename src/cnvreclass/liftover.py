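"""Genome-build conversion of CNV intervals through UCSC chain files.

CNV boundaries are breakpoint estimates, not base alignments, so intervals
are lifted with span semantics: the image is the min..max of the mapped
bases' images within the best-scoring chain.  Chain files use 0-based
half-open coordinates on both sides; conversion to the package's 1-based
inclusive convention happens at this module's boundary.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

from intervaltree import IntervalTree

from .core import (
    Assembly,
    AssemblyMismatchError,
    CNVCall,
    GenomicInterval,
    ValidationError,
    normalize_chrom,
)

__all__ = [
    "ChainBlock",
    "Chain",
    "ChainSet",
    "ChainParseError",
    "LiftStatus",
    "LiftResult",
    "read_chain",
    "lift_interval",
    "lift_cohort",
]


class ChainParseError(ValueError):
    def __init__(self, message: str, line_number: int = -1):
        self.line_number = line_number
        if line_number >= 0:
            message = f"{message} (line {line_number})"
        super().__init__(message)


@dataclass(frozen=True)
class ChainBlock:
    """One ungapped aligned block, 0-based half-open on both assemblies."""

    t_start: int  # source assembly
    q_start: int  # target assembly (on the chain's q strand)
    size: int


@dataclass
class Chain:
    """One chain: a co-linear set of aligned blocks between two sequences."""

    score: int
    t_name: str
    t_size: int
    t_start: int
    t_end: int
    q_name: str
    q_size: int
    q_strand: str
    q_start: int
    q_end: int
    chain_id: str
    blocks: list = field(default_factory=list)

    def q_plus_coord(self, q0: int) -> int:
        """Map a 0-based q-strand coordinate to the + strand of the target."""
        if self.q_strand == "+":
            return q0
        return self.q_size - 1 - q0


_CHAIN_HEADER_RE = re.compile(r"^chain\s+")


def read_chain(
    path,
    source_assembly: Assembly = None,
    target_assembly: Assembly = None,
) -> "ChainSet":
    """Parse a UCSC chain file into an indexed :class:`ChainSet`.

    Assemblies may be given explicitly or are sniffed from UCSC-convention
    file names such as ``hg18ToHg19.over.chain``.
    """
    path = Path(path)
    if source_assembly is None or target_assembly is None:
        m = re.search(r"(hg\d+)To(Hg\d+)", path.name)
        if m:
            source_assembly = source_assembly or Assembly.from_tag(m.group(1))
            target_assembly = target_assembly or Assembly.from_tag(m.group(2).lower())
        else:
            source_assembly = source_assembly or Assembly.UNSPECIFIED
            target_assembly = target_assembly or Assembly.UNSPECIFIED

    chains: list[Chain] = []
    current: Optional[Chain] = None
    t_cursor = q_cursor = 0
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if _CHAIN_HEADER_RE.match(line):
                if current is not None and current.blocks and not _chain_closed(current):
                    raise ChainParseError("chain not terminated by a bare size line", ln)
                parts = line.split()
                if len(parts) != 13:
                    raise ChainParseError(
                        f"chain header has {len(parts)} fields, expected 13", ln
                    )
                try:
                    current = Chain(
                        score=int(parts[1]),
                        t_name=parts[2],
                        t_size=int(parts[3]),
                        t_start=int(parts[5]),
                        t_end=int(parts[6]),
                        q_name=parts[7],
                        q_size=int(parts[8]),
                        q_strand=parts[9],
                        q_start=int(parts[10]),
                        q_end=int(parts[11]),
                        chain_id=parts[12],
                    )
                except ValueError:
                    raise ChainParseError("non-numeric field in chain header", ln)
                if parts[4] != "+":
                    raise ChainParseError("source (t) strand must be '+'", ln)
                if current.q_strand not in "+-":
                    raise ChainParseError(f"bad q strand {current.q_strand!r}", ln)
                t_cursor, q_cursor = current.t_start, current.q_start
                chains.append(current)
                continue
            if current is None:
                raise ChainParseError("alignment line before any chain header", ln)
            parts = line.split()
            if len(parts) not in (1, 3):
                raise ChainParseError("alignment line must have 1 or 3 fields", ln)
            try:
                nums = [int(p) for p in parts]
            except ValueError:
                raise ChainParseError("non-numeric alignment field", ln)
            size = nums[0]
            current.blocks.append(ChainBlock(t_cursor, q_cursor, size))
            if len(nums) == 3:
                dt, dq = nums[1], nums[2]
                t_cursor += size + dt
                q_cursor += size + dq
            else:
                t_cursor += size
                q_cursor += size
                current = _validate_chain(current, ln)
                current = None
    if not chains:
        raise ChainParseError("empty chain file")
    if current is not None:
        raise ChainParseError("last chain not terminated by a bare size line")
    return ChainSet(chains, source_assembly, target_assembly)


def _chain_closed(chain: Chain) -> bool:
    last = chain.blocks[-1]
    return last.t_start + last.size == chain.t_end


def _validate_chain(chain: Chain, ln: int) -> Chain:
    last = chain.blocks[-1]
    if last.t_start + last.size != chain.t_end:
        raise ChainParseError(
            f"chain {chain.chain_id}: blocks end at {last.t_start + last.size}, "
            f"header says tEnd={chain.t_end}",
            ln,
        )
    return chain


class ChainSet:
    """Chains indexed by source chromosome for interval queries."""

    def __init__(self, chains, source_assembly: Assembly, target_assembly: Assembly):
        self.chains = list(chains)
        self.source_assembly = source_assembly
        self.target_assembly = target_assembly
        self._index: dict = {}
        for chain in self.chains:
            chrom = normalize_chrom(chain.t_name)
            tree = self._index.setdefault(chrom, IntervalTree())
            if chain.t_end > chain.t_start:
                tree.addi(chain.t_start, chain.t_end, chain)

    def overlapping(self, chrom: str, start0: int, end0: int):
        """Chains whose source span overlaps [start0, end0) (0-based half-open)."""
        tree = self._index.get(normalize_chrom(chrom))
        if tree is None:
            return []
        return sorted(
            (iv.data for iv in tree.overlap(start0, end0)),
            key=lambda c: -c.score,
        )


class LiftStatus(str, enum.Enum):
    MAPPED = "mapped"
    PARTIAL = "partial"
    SPLIT = "split"
    UNMAPPED = "unmapped"


@dataclass
class LiftResult:
    status: LiftStatus
    mapped_interval: Optional[GenomicInterval]
    mapped_fraction: float
    notes: str = ""


def _chain_image(chain: Chain, start0: int, end0: int):
    """Aligned-base count and +strand image span of [start0, end0) in one chain."""
    mapped = 0
    lo = hi = None
    for block in chain.blocks:
        b_lo = max(block.t_start, start0)
        b_hi = min(block.t_start + block.size, end0)
        if b_hi <= b_lo:
            continue
        mapped += b_hi - b_lo
        q_lo = block.q_start + (b_lo - block.t_start)
        q_hi = q_lo + (b_hi - b_lo) - 1  # inclusive last base, q strand
        for q0 in (q_lo, q_hi):
            plus = chain.q_plus_coord(q0)
            lo = plus if lo is None else min(lo, plus)
            hi = plus if hi is None else max(hi, plus)
    return mapped, lo, hi


def lift_interval(
    interval: GenomicInterval,
    chains: ChainSet,
    min_match: float = 0.95,
) -> LiftResult:
    """Lift one interval; span semantics over the best-scoring covering chain.

    ``min_match`` is the minimum fraction of source bases that must fall in
    aligned blocks of a single chain for status ``mapped`` (0.95 follows the
    UCSC liftOver default).
    """
    if not (0 < min_match <= 1):
        raise ValueError(f"min_match must be in (0, 1], got {min_match}")
    if (
        interval.assembly != Assembly.UNSPECIFIED
        and chains.source_assembly != Assembly.UNSPECIFIED
        and interval.assembly != chains.source_assembly
    ):
        raise AssemblyMismatchError(
            f"interval on {interval.assembly.value} but chain source is "
            f"{chains.source_assembly.value}"
        )
    start0, end0 = interval.start - 1, interval.end  # to 0-based half-open
    candidates = chains.overlapping(interval.chrom, start0, end0)
    scored = []
    for chain in candidates:
        mapped, lo, hi = _chain_image(chain, start0, end0)
        if mapped > 0:
            scored.append((chain, mapped, lo, hi))
    if not scored:
        return LiftResult(LiftStatus.UNMAPPED, None, 0.0, "no chain covers interval")
    best = max(scored, key=lambda t: (t[1], t[0].score))
    chain, mapped, lo, hi = best
    fraction = mapped / interval.length
    target_chrom = normalize_chrom(chain.q_name)
    image = GenomicInterval(target_chrom, lo + 1, hi + 1, chains.target_assembly)
    if fraction >= min_match:
        return LiftResult(
            LiftStatus.MAPPED, image, fraction, f"chain {chain.chain_id}"
        )
    if len(scored) > 1:
        return LiftResult(
            LiftStatus.SPLIT,
            image,
            fraction,
            f"best chain {chain.chain_id} covers {fraction:.3f} < {min_match}; "
            f"{len(scored)} chains overlap",
        )
    return LiftResult(
        LiftStatus.PARTIAL,
        image,
        fraction,
        f"chain {chain.chain_id} covers {fraction:.3f} < {min_match}",
    )


def lift_cohort(
    calls: Iterable[CNVCall],
    chains: ChainSet,
    min_match: float = 0.95,
):
    """Batch lift; returns (lifted calls, exception report rows).

    Calls whose interval maps cleanly get updated coordinates and assembly;
    partial/split/unmapped calls go to the report and are never silently
    dropped.
    """
    lifted: list[CNVCall] = []
    report: list[dict] = []
    for call in calls:
        res = lift_interval(call.interval, chains, min_match)
        if res.status is LiftStatus.MAPPED:
            lifted.append(replace(call, interval=res.mapped_interval))
        else:
            report.append(
                {
                    "id": call.id,
                    "interval": str(call.interval),
                    "status": res.status.value,
                    "mapped_fraction": round(res.mapped_fraction, 4),
                    "notes": res.notes,
                }
            )
    return lifted, report
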