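"""Single-primer-pair assay design from a homologous segment pair.

Given an aligned pair of near-identical segments differing by a small net
indel, this module finds conserved primer-length stretches flanking the
indel, emits one (possibly degenerate) primer pair that amplifies both
segments, applies the universal M13-40 forward tail and the PIG-tail
reverse extension used for fluorescent labelling and clean adenylation,
and quality-controls the pair (GC content, nearest-neighbor melting
temperature, mispriming against a supplied genome).

The 3'-terminal three bases of every primer are required to be
non-degenerate and to match both templates exactly, since polymerase
extension needs a matched 3' terminus.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

from Bio.SeqUtils import MeltingTemp as _mt

from .homolog_finder import HomologyPair, PairwiseAlignment
from .seqcore import (
    CONCRETE_BASES,
    IUPAC_EXPAND,
    GenomicInterval,
    Primer,
    SeqRecord,
    ambiguity_code,
    revcomp,
)

logger = logging.getLogger(__name__)

#: Universal M13-40 extension appended 5' of the forward primer.
M13_40_TAIL = "GTTTTCCCAGTCACGAC"
#: PIG-tail extension appended 5' of the reverse primer.
PIG_TAIL = "GTTTCTT"
#: Electrophoretic size a tailed product gains over its genomic span.
TAIL_BP = len(M13_40_TAIL) + len(PIG_TAIL)  # 24


@dataclass(frozen=True)
class DesignParams:
    """Tunable assay-design constraints."""

    stretch_min: int = 15          # shortest usable conserved stretch (bp)
    stretch_max: int = 25          # primers are trimmed to at most this
    max_degenerate: int = 2        # degenerate positions tolerated per primer
    primer_opt_len: int = 20
    product_range: tuple[int, int] = (80, 300)   # untailed size bounds
    gc_range: tuple[float, float] = (0.30, 0.70)
    tm_range: tuple[float, float] = (52.0, 65.0)
    forward_tail: str = M13_40_TAIL
    reverse_tail: str = PIG_TAIL
    max_assays: int = 10


@dataclass(frozen=True)
class ConservedStretch:
    """A maximal gap-free alignment window usable as a primer site."""

    start: int              # alignment column of first position
    length: int
    mismatch_count: int
    consensus: str          # IUPAC, degenerate at mismatch columns

    def __post_init__(self) -> None:
        if len(self.consensus) != self.length:
            raise ValueError("consensus length mismatch")

    @property
    def end(self) -> int:
        return self.start + self.length


@dataclass
class QCReport:
    """Primer-pair quality control summary."""

    gc_fraction: dict[str, float]
    tm_celsius: dict[str, float]
    mispriming_sites: Optional[int]   # None until checked against a genome
    hairpin_flag: bool
    passed: bool
    notes: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class PlannedAmplicon:
    """One of the two products an assay is designed to yield."""

    interval: GenomicInterval
    size_untailed: int
    size_tailed: int
    role: str  # test | control


@dataclass
class CandidateAssay:
    """A designed primer pair and its two expected products."""

    name: str
    forward: Primer
    reverse: Primer
    amplicons: list[PlannedAmplicon]
    delta_size: int
    qc: Optional[QCReport] = None

    def __post_init__(self) -> None:
        if len(self.amplicons) != 2:
            raise ValueError("an assay must define exactly two amplicons")
        sizes = {a.size_untailed for a in self.amplicons}
        if len(sizes) != 2:
            raise ValueError("amplicon sizes must be distinct")
        if not (1 <= abs(self.delta_size) <= 10):
            raise ValueError("|delta_size| must lie in [1, 10]")

    @property
    def test_amplicon(self) -> PlannedAmplicon:
        return next(a for a in self.amplicons if a.role == "test")

    @property
    def control_amplicon(self) -> PlannedAmplicon:
        return next(a for a in self.amplicons if a.role == "control")


# --------------------------------------------------------------------------
# conserved stretches
# --------------------------------------------------------------------------

def find_conserved_stretches(
    aln: PairwiseAlignment, min_len: int = 15, max_mismatch: int = 2
) -> list[ConservedStretch]:
    """All maximal gap-free windows of length >= min_len with <= max_mismatch
    mismatches; consensus carries IUPAC ambiguity codes at mismatch columns."""
    aq, asub = aln.aligned_query, aln.aligned_subject
    if not aq:
        raise ValueError("empty alignment")
    # split into gap-free segments
    segments: list[tuple[int, int]] = []  # [start col, end col)
    start = None
    for col, (q, s) in enumerate(zip(aq, asub)):
        if q == "-" or s == "-":
            if start is not None:
                segments.append((start, col))
                start = None
        elif start is None:
            start = col
    if start is not None:
        segments.append((start, len(aq)))

    out: list[ConservedStretch] = []
    for seg_start, seg_end in segments:
        n = seg_end - seg_start
        mism = [aq[seg_start + i] != asub[seg_start + i] for i in range(n)]
        r = 0
        count = 0
        prev_r = -1
        for l in range(n):
            if r < l:
                r = l
                count = 0
            while r < n and count + (1 if mism[r] else 0) <= max_mismatch:
                count += 1 if mism[r] else 0
                r += 1
            # window [l, r) is maximal-right; keep if not contained in previous
            if (l == 0 or r > prev_r) and r - l >= min_len:
                cons = "".join(
                    aq[seg_start + i]
                    if not mism[i]
                    else ambiguity_code([aq[seg_start + i], asub[seg_start + i]])
                    for i in range(l, r)
                )
                out.append(
                    ConservedStretch(
                        start=seg_start + l,
                        length=r - l,
                        mismatch_count=sum(mism[l:r]),
                        consensus=cons,
                    )
                )
            prev_r = r
            if mism[l]:
                count -= 1
    return out


# --------------------------------------------------------------------------
# assay design
# --------------------------------------------------------------------------

def _degenerate_count(seq: str) -> int:
    return sum(1 for c in seq if c not in CONCRETE_BASES)


def _pick_primer_window(
    stretch: ConservedStretch, side: str, params: DesignParams
) -> Optional[tuple[int, int]]:
    """Choose a primer window (stretch-relative [start, end)) inside a stretch.

    ``side`` 'left' yields the forward primer (3' end rightmost, pushed
    toward the indel); 'right' yields the reverse primer (3' end leftmost).
    The 3'-terminal 3 consensus bases must be concrete.
    """
    cons = stretch.consensus
    n = len(cons)
    lengths = sorted(
        range(params.stretch_min, min(n, params.stretch_max) + 1),
        key=lambda L: (abs(L - params.primer_opt_len), -L),
    )
    for L in lengths:
        offsets = range(n - L, -1, -1) if side == "left" else range(0, n - L + 1)
        for off in offsets:
            win = cons[off : off + L]
            if _degenerate_count(win) > params.max_degenerate:
                continue
            three_prime = win[-3:] if side == "left" else win[:3]
            if any(c not in CONCRETE_BASES for c in three_prime):
                continue
            return off, L
    return None


def _position_maps(aln: PairwiseAlignment) -> tuple[list[Optional[int]], list[Optional[int]]]:
    qmap: list[Optional[int]] = []
    smap: list[Optional[int]] = []
    qi = si = 0
    for q, s in zip(aln.aligned_query, aln.aligned_subject):
        qmap.append(qi if q != "-" else None)
        smap.append(si if s != "-" else None)
        if q != "-":
            qi += 1
        if s != "-":
            si += 1
    return qmap, smap


def _genomic(iv: GenomicInterval, seg_pos_start: int, seg_pos_end: int) -> GenomicInterval:
    """Map segment-relative 0-based [start, end] positions to genomic coords."""
    if iv.strand == "+":
        return GenomicInterval(iv.chrom, iv.start + seg_pos_start, iv.start + seg_pos_end)
    return GenomicInterval(
        iv.chrom, iv.end - seg_pos_end, iv.end - seg_pos_start, strand="-"
    )


def design_assay(
    pair: HomologyPair,
    params: DesignParams = DesignParams(),
    name_prefix: Optional[str] = None,
) -> list[CandidateAssay]:
    """Design candidate single-primer-pair assays for a homologous pair.

    Forward primers come from conserved stretches left of the leftmost
    indel, reverse primers (reverse-complemented consensus) from stretches
    right of the rightmost indel, so both products span the diagnostic
    length difference.  Returns assays sorted by QC pass then smaller
    product size; empty with a logged reason when no flanking stretch exists.
    """
    aln = pair.alignment
    if not aln.indel_blocks:
        raise ValueError("homology pair has no indel (delta = 0): products would be unresolvable")
    left_edge = min(col for col, _, _ in aln.indel_blocks)
    right_edge = max(col + length for col, length, _ in aln.indel_blocks)
    stretches = find_conserved_stretches(aln, params.stretch_min, params.max_degenerate)
    lefts = [st for st in stretches if st.end <= left_edge]
    rights = [st for st in stretches if st.start >= right_edge]
    if not lefts:
        logger.warning("no conserved stretch left of the indel; no assay designed")
        return []
    if not rights:
        logger.warning("no conserved stretch right of the indel; no assay designed")
        return []

    qmap, smap = _position_maps(aln)
    prefix = name_prefix or f"{pair.query_iv.chrom}_{pair.query_iv.start}"
    assays: list[CandidateAssay] = []
    for lf in lefts:
        fwin = _pick_primer_window(lf, "left", params)
        if fwin is None:
            continue
        f_off, f_len = fwin
        fs, fe = lf.start + f_off, lf.start + f_off + f_len
        fwd_core = lf.consensus[f_off : f_off + f_len]
        for rt in rights:
            rwin = _pick_primer_window(rt, "right", params)
            if rwin is None:
                continue
            r_off, r_len = rwin
            rs, re = rt.start + r_off, rt.start + r_off + r_len
            rev_core = revcomp(rt.consensus[r_off : r_off + r_len])

            q_start, q_end = qmap[fs], qmap[re - 1]
            s_start, s_end = smap[fs], smap[re - 1]
            assert None not in (q_start, q_end, s_start, s_end)
            q_size = q_end - q_start + 1
            s_size = s_end - s_start + 1
            lo, hi = params.product_range
            if not (lo <= q_size <= hi and lo <= s_size <= hi) or q_size == s_size:
                continue
            delta_size = q_size - s_size
            if abs(delta_size) > 10:
                continue
            n = len(assays)
            fwd = Primer(f"{prefix}_F{n}", fwd_core, tail=params.forward_tail, role="forward")
            rev = Primer(f"{prefix}_R{n}", rev_core, tail=params.reverse_tail, role="reverse")
            tail_bp = len(params.forward_tail) + len(params.reverse_tail)
            amplicons = [
                PlannedAmplicon(
                    interval=_genomic(pair.query_iv, q_start, q_end),
                    size_untailed=q_size,
                    size_tailed=q_size + tail_bp,
                    role="test",
                ),
                PlannedAmplicon(
                    interval=_genomic(pair.subject_iv, s_start, s_end),
                    size_untailed=s_size,
                    size_tailed=s_size + tail_bp,
                    role="control",
                ),
            ]
            assay = CandidateAssay(
                name=f"{prefix}_assay{n}",
                forward=fwd,
                reverse=rev,
                amplicons=amplicons,
                delta_size=delta_size,
            )
            assay.qc = _sequence_qc(assay, params)
            assays.append(assay)
            if len(assays) >= params.max_assays:
                break
        if len(assays) >= params.max_assays:
            break

    assays.sort(key=lambda a: (not (a.qc.passed if a.qc else False),
                               min(x.size_untailed for x in a.amplicons)))
    return assays


# --------------------------------------------------------------------------
# quality control
# --------------------------------------------------------------------------

_GC_WEIGHT = {"G": 1.0, "C": 1.0, "S": 1.0, "A": 0.0, "T": 0.0, "W": 0.0}


def gc_fraction(core: str) -> float:
    """GC fraction of a (possibly degenerate) primer core.

    Degenerate bases contribute their expected GC: S = 1, W = 0, all other
    ambiguity codes 0.5.
    """
    if not core:
        raise ValueError("empty primer core")
    return sum(_GC_WEIGHT.get(c, 0.5) for c in core.upper()) / len(core)


def _highest_at_expansion(core: str) -> str:
    """The concrete expansion with the most A/T (conservative for Tm)."""
    pref = {b: i for i, b in enumerate("ATCG")}
    return "".join(
        min(IUPAC_EXPAND[c], key=lambda b: pref[b]) for c in core.upper()
    )


def melting_temp(core: str, na_mM: float = 50.0, primer_nM: float = 250.0) -> float:
    """Nearest-neighbor Tm (deg C) of a primer core.

    Degenerate cores are evaluated on their highest-AT concrete expansion,
    which gives the lowest (most conservative) Tm.
    """
    seq = _highest_at_expansion(core)
    return float(_mt.Tm_NN(seq, dnac1=primer_nM, dnac2=0, Na=na_mM))


def _self_complementary_run(seq: str) -> int:
    """Longest perfect complementary run between a sequence and itself."""
    rc = revcomp(seq)
    best = 0
    for k in range(len(seq), 3, -1):
        if best >= k:
            break
        for i in range(len(seq) - k + 1):
            if seq[i : i + k] in rc:
                best = max(best, k)
                break
    return best


def _sequence_qc(assay: CandidateAssay, params: DesignParams) -> QCReport:
    """Sequence-only QC (no genome): GC, Tm, hairpin/self-dimer heuristic."""
    gc = {"forward": gc_fraction(assay.forward.core), "reverse": gc_fraction(assay.reverse.core)}
    tm = {"forward": melting_temp(assay.forward.core), "reverse": melting_temp(assay.reverse.core)}
    hairpin = any(
        _self_complementary_run(p.core) >= 8 for p in (assay.forward, assay.reverse)
    )
    glo, ghi = params.gc_range
    tlo, thi = params.tm_range
    notes = []
    ok = True
    for role in ("forward", "reverse"):
        if not (glo <= gc[role] <= ghi):
            ok = False
            notes.append(f"{role} GC {gc[role]:.2f} outside [{glo}, {ghi}]")
        if not (tlo <= tm[role] <= thi):
            ok = False
            notes.append(f"{role} Tm {tm[role]:.1f} outside [{tlo}, {thi}]")
    return QCReport(
        gc_fraction=gc,
        tm_celsius=tm,
        mispriming_sites=None,
        hairpin_flag=hairpin,
        passed=ok,
        notes=notes,
    )


def primer_qc(
    assay: CandidateAssay,
    genome: list[SeqRecord],
    params: DesignParams = DesignParams(),
    max_mismatch: int = 2,
) -> QCReport:
    """Full QC including mispriming against ``genome``.

    Each primer is expected to bind exactly twice (once per homologous
    segment); any further binding site counts as mispriming.  Overall pass
    requires GC and Tm in range for both primers and zero mispriming sites.
    """
    if not genome:
        raise ValueError("genome must be non-empty")
    from .insilico_pcr import find_binding_sites  # local import avoids a cycle

    base = _sequence_qc(assay, params)
    extra = 0
    for primer in (assay.forward, assay.reverse):
        n_sites = sum(
            len(find_binding_sites(primer, rec, max_mismatch=max_mismatch))
            for rec in genome
        )
        extra += max(0, n_sites - 2)
    notes = list(base.notes)
    if extra:
        notes.append(f"{extra} mispriming site(s) beyond the two intended")
    report = QCReport(
        gc_fraction=base.gc_fraction,
        tm_celsius=base.tm_celsius,
        mispriming_sites=extra,
        hairpin_flag=base.hairpin_flag,
        passed=base.passed and extra == 0,
        notes=notes,
    )
    assay.qc = report
    return report


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def assay_to_dict(assay: CandidateAssay) -> dict:
    return {
        "name": assay.name,
        "forward": {"name": assay.forward.name, "core": assay.forward.core, "tail": assay.forward.tail},
        "reverse": {"name": assay.reverse.name, "core": assay.reverse.core, "tail": assay.reverse.tail},
        "amplicons": [
            {
                "chrom": a.interval.chrom,
                "start": a.interval.start,
                "end": a.interval.end,
                "strand": a.interval.strand,
                "size": a.size_tailed,
                "size_untailed": a.size_untailed,
                "role": a.role,
            }
            for a in assay.amplicons
        ],
        "delta_size": assay.delta_size,
    }


def assay_from_dict(d: dict) -> CandidateAssay:
    amplicons = [
        PlannedAmplicon(
            interval=GenomicInterval(
                a["chrom"], a["start"], a["end"], strand=a.get("strand", "+")
            ),
            size_untailed=a.get("size_untailed", a["size"] - TAIL_BP),
            size_tailed=a["size"],
            role=a["role"],
        )
        for a in d["amplicons"]
    ]
    return CandidateAssay(
        name=d["name"],
        forward=Primer(d["forward"].get("name", d["name"] + "_F"),
                       d["forward"]["core"], tail=d["forward"].get("tail", ""), role="forward"),
        reverse=Primer(d["reverse"].get("name", d["name"] + "_R"),
                       d["reverse"]["core"], tail=d["reverse"].get("tail", ""), role="reverse"),
        amplicons=amplicons,
        delta_size=d["delta_size"],
    )


def assay_to_json(assay: CandidateAssay, **json_kwargs) -> str:
    json_kwargs.setdefault("indent", 2)
    return json.dumps(assay_to_dict(assay), **json_kwargs)


def assay_from_json(text: str) -> CandidateAssay:
    return assay_from_dict(json.loads(text))


def assays_to_tsv(assays: Iterable[CandidateAssay]) -> str:
    """Primer list as TSV mirroring a published primer-table layout."""
    lines = ["assay\tprimer\tsequence_5to3\tfragment_size\tlocation"]
    for a in assays:
        for primer, amp in ((a.forward, a.test_amplicon), (a.reverse, a.control_amplicon)):
            lines.append(
                f"{a.name}\t{primer.name}\t{primer.full}\t{amp.size_tailed}"
                f"\t{amp.interval.chrom}:{amp.interval.start}-{amp.interval.end}"
            )
    return "\n".join(lines) + "\n"
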