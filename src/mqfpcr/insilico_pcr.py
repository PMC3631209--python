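"""Degenerate-aware in-silico PCR.

Finds primer binding sites on both strands of concrete template sequence,
enumerates properly oriented products, screens candidate assays against
exclusion intervals (known CNVs/SNPs), and validates that an assay yields
exactly the two size-resolvable products it was designed for.

Matching rules: a primer core binds where every position matches under the
IUPAC expansion with at most ``max_mismatch`` mismatches, except the
3'-terminal ``THREE_PRIME_EXACT`` bases which must match exactly (primer
extension requires a matched 3' terminus).  Universal tails never take part
in template matching; they only add to the electrophoretic product size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .primer_design import CandidateAssay, PlannedAmplicon
from .seqcore import (
    GenomicInterval,
    IUPAC_EXPAND,
    Primer,
    SeqRecord,
    revcomp,
)

logger = logging.getLogger(__name__)

#: 3'-terminal bases of the core that must match the template exactly.
THREE_PRIME_EXACT = 5

#: Largest product considered during enumeration.
MAX_PRODUCT_SIZE = 1000


@dataclass(frozen=True)
class BindingSite:
    """A primer-core footprint on a template (1-based inclusive, + strand coords)."""

    chrom: str
    start: int
    end: int
    strand: str
    mismatch_count: int


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product, spanning outermost primer-core footprints."""

    chrom: str
    start: int
    end: int
    size_untailed: int
    size_tailed: int
    strand: str = "+"
    role: str = "offtarget"
    mismatches: int = 0

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end)


def _match_at(core: str, seq: str, pos: int, max_mismatch: int, exact_idx: range) -> Optional[int]:
    """Mismatch count if ``core`` (as laid on + strand) binds at ``pos``; None if not."""
    mismatches = 0
    # exact 3'-end positions first: cheap rejection
    for i in exact_idx:
        if seq[pos + i] not in IUPAC_EXPAND[core[i]]:
            return None
    for i in range(len(core)):
        if i in exact_idx:
            continue
        if seq[pos + i] not in IUPAC_EXPAND[core[i]]:
            mismatches += 1
            if mismatches > max_mismatch:
                return None
    return mismatches


def find_binding_sites(
    primer: Primer,
    template: SeqRecord,
    max_mismatch: int = 2,
    three_prime_exact: int = THREE_PRIME_EXACT,
) -> list[BindingSite]:
    """All positions on both strands where the primer core binds.

    The template must be concrete sequence; only the primer may carry
    degenerate bases.  Tails are ignored.
    """
    core = primer.core
    L = len(core)
    seq = template.seq
    if any(c not in "ACGT" for c in seq):
        raise ValueError(f"template {template.id!r} contains degenerate bases")
    sites: list[BindingSite] = []
    tp = min(three_prime_exact, L)
    for strand in ("+", "-"):
        if strand == "+":
            pat = core
            exact_idx = range(L - tp, L)   # 3' end is rightmost
        else:
            pat = revcomp(core)
            exact_idx = range(0, tp)       # 3' end maps to leftmost position
        for pos in range(len(seq) - L + 1):
            mm = _match_at(pat, seq, pos, max_mismatch, exact_idx)
            if mm is not None:
                sites.append(
                    BindingSite(
                        chrom=template.id,
                        start=pos + 1,
                        end=pos + L,
                        strand=strand,
                        mismatch_count=mm,
                    )
                )
    return sites


def enumerate_amplicons(
    fwd: Primer,
    rev: Primer,
    templates: Iterable[SeqRecord],
    size_range: tuple[int, int] = (1, MAX_PRODUCT_SIZE),
    max_mismatch: int = 2,
) -> list[Amplicon]:
    """Every properly oriented product within the untailed size range.

    A product needs the forward primer on + and the reverse on - with the
    forward footprint 5' of the reverse one, or the strand-mirrored
    arrangement.  Sizes are measured outermost-to-outermost of the core
    footprints; tailed size adds both tail lengths.
    """
    lo, hi = size_range
    if lo <= 0 or hi < lo:
        raise ValueError("size range must be positive")
    tail_bp = len(fwd.tail) + len(rev.tail)
    out: list[Amplicon] = []
    for rec in templates:
        fsites = find_binding_sites(fwd, rec, max_mismatch=max_mismatch)
        rsites = find_binding_sites(rev, rec, max_mismatch=max_mismatch)
        for f in fsites:
            for r in rsites:
                if f.strand == "+" and r.strand == "-" and f.start <= r.start:
                    start, end = f.start, r.end
                    strand = "+"
                elif f.strand == "-" and r.strand == "+" and r.start <= f.start:
                    start, end = r.start, f.end
                    strand = "-"
                else:
                    continue
                size = end - start + 1
                if lo <= size <= hi:
                    out.append(
                        Amplicon(
                            chrom=rec.id,
                            start=start,
                            end=end,
                            size_untailed=size,
                            size_tailed=size + tail_bp,
                            strand=strand,
                            mismatches=f.mismatch_count + r.mismatch_count,
                        )
                    )
    out.sort(key=lambda a: (a.chrom, a.start, a.end))
    return out


def screen_exclusions(
    assay: CandidateAssay, exclusions: Sequence[GenomicInterval]
) -> tuple[bool, list[tuple[PlannedAmplicon, GenomicInterval]]]:
    """Screen assay footprints against exclusion intervals (known CNVs/SNPs).

    Fails when any amplicon interval (which spans both primer footprints)
    overlaps an exclusion by >= 1 bp.  Chromosomes absent from the
    exclusion set are treated as overlap-free (logged).
    """
    excl_chroms = {iv.chrom for iv in exclusions}
    overlaps: list[tuple[PlannedAmplicon, GenomicInterval]] = []
    for amp in assay.amplicons:
        if amp.interval.chrom not in excl_chroms:
            logger.info(
                "chromosome %s not present in exclusion set; assuming clear",
                amp.interval.chrom,
            )
            continue
        for iv in exclusions:
            if amp.interval.overlaps(iv):
                overlaps.append((amp, iv))
    return (len(overlaps) == 0, overlaps)


@dataclass
class ValidationReport:
    """Outcome of in-silico validation of a candidate assay."""

    valid: bool
    n_products: int
    amplicons: list[Amplicon]
    reason: str = ""


def _assign_roles(amplicons: list[Amplicon], assay: CandidateAssay) -> list[Amplicon]:
    """Label observed products test/control by matching planned intervals, then sizes."""
    out = []
    for amp in amplicons:
        role = "offtarget"
        for planned in assay.amplicons:
            same_chrom = amp.chrom == planned.interval.chrom
            if same_chrom and amp.interval.overlaps(planned.interval):
                role = planned.role
                break
            if amp.size_untailed == planned.size_untailed and role == "offtarget":
                role = planned.role
        out.append(
            Amplicon(
                chrom=amp.chrom, start=amp.start, end=amp.end,
                size_untailed=amp.size_untailed, size_tailed=amp.size_tailed,
                strand=amp.strand, role=role, mismatches=amp.mismatches,
            )
        )
    return out


def validate_assay(
    assay: CandidateAssay,
    genome: Iterable[SeqRecord],
    max_mismatch: int = 2,
    size_range: tuple[int, int] = (1, MAX_PRODUCT_SIZE),
) -> ValidationReport:
    """Valid iff the assay yields exactly two products with distinct sizes
    differing by 1-10 bp on the supplied genome."""
    products = enumerate_amplicons(
        assay.forward, assay.reverse, list(genome),
        size_range=size_range, max_mismatch=max_mismatch,
    )
    n = len(products)
    if n != 2:
        return ValidationReport(
            valid=False, n_products=n, amplicons=products,
            reason=f"expected 2 products, found {n}",
        )
    sizes = sorted(p.size_untailed for p in products)
    diff = sizes[1] - sizes[0]
    if diff == 0:
        return ValidationReport(
            valid=False, n_products=2, amplicons=products,
            reason="unresolvable: both products have equal size",
        )
    if diff > 10:
        return ValidationReport(
            valid=False, n_products=2, amplicons=products,
            reason=f"size difference {diff} bp outside 1-10 bp",
        )
    return ValidationReport(
        valid=True, n_products=2, amplicons=_assign_roles(products, assay)
    )


def amplicons_to_tsv(amplicons: Iterable[Amplicon]) -> str:
    lines = ["chrom\tstart\tend\tsize_untailed\tsize_tailed\tstrand\trole\tmismatches"]
    for a in amplicons:
        lines.append(
            f"{a.chrom}\t{a.start}\t{a.end}\t{a.size_untailed}\t{a.size_tailed}"
            f"\t{a.strand}\t{a.role}\t{a.mismatches}"
        )
    return "\n".join(lines) + "\n"
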