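"""Detection of paralogous segment pairs suitable for single-primer-pair dosage assays.

The search emulates a BLASTN screen of a disease critical region against
candidate genomic sequence: long regions are tiled into 100-200 kb chunks,
each chunk is scanned for highly similar segments elsewhere whose lengths
differ by a small net indel (1-10 bp by default).  That length difference
is what later resolves the two co-amplified products on a capillary.

Algorithm: k-mer seeding (k = 15, the scale of a conserved primer site),
diagonal clustering of seeds, then banded gapped extension via local
alignment of the seeded windows.  A full Smith-Waterman dynamic program is
used only as an independent oracle in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align

from .seqcore import GenomicInterval, SeqRecord, revcomp


@dataclass(frozen=True)
class AlignScoring:
    """BLASTN-like affine gap scoring: a gap of length L costs open + L * extend."""

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -5.0
    gap_extend: float = -2.0


DEFAULT_SCORING = AlignScoring()


@dataclass
class PairwiseAlignment:
    """A gapped pairwise alignment plus summary statistics.

    ``indel_blocks`` lists every maximal gap run as
    (alignment column, length, which sequence is gapped).
    Identity is matches / alignment columns (gap columns count in the
    denominator, as in BLAST).
    """

    aligned_query: str
    aligned_subject: str
    score: float
    identity: float = field(init=False)
    indel_blocks: list[tuple[int, int, str]] = field(init=False)

    def __post_init__(self) -> None:
        aq, asub = self.aligned_query, self.aligned_subject
        if len(aq) != len(asub):
            raise ValueError("gapped strings differ in length")
        matches = 0
        blocks: list[tuple[int, int, str]] = []
        open_block: Optional[tuple[int, str]] = None  # (start col, gapped side)
        for col, (q, s) in enumerate(zip(aq, asub)):
            if q == "-" and s == "-":
                raise ValueError(f"column {col}: gap in both sequences")
            if q == "-" or s == "-":
                side = "query" if q == "-" else "subject"
                if open_block is not None and open_block[1] == side:
                    continue
                if open_block is not None:
                    blocks.append((open_block[0], col - open_block[0], open_block[1]))
                open_block = (col, side)
            else:
                if open_block is not None:
                    blocks.append((open_block[0], col - open_block[0], open_block[1]))
                    open_block = None
                if q == s:
                    matches += 1
        if open_block is not None:
            blocks.append((open_block[0], len(aq) - open_block[0], open_block[1]))
        self.identity = matches / len(aq) if aq else 0.0
        self.indel_blocks = blocks

    @property
    def delta(self) -> int:
        """Net length difference, ungapped query minus ungapped subject."""
        q = sum(1 for c in self.aligned_query if c != "-")
        s = sum(1 for c in self.aligned_subject if c != "-")
        return q - s

    def __len__(self) -> int:
        return len(self.aligned_query)


@dataclass
class HomologyPair:
    """A (critical-region segment, control segment) couple.

    ``delta`` is the signed net length difference (query - subject) that
    makes the two amplicons electrophoretically distinguishable.
    Subject intervals are always reported on the + strand; ``subject_iv.strand``
    records which strand carried the homology.
    """

    query_iv: GenomicInterval
    subject_iv: GenomicInterval
    identity: float
    delta: int
    alignment: PairwiseAlignment
    score: float
    query_seq: str = ""
    subject_seq: str = ""


def _make_aligner(scoring: AlignScoring, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    # Biopython charges open_gap_score for the first gapped position and
    # extend_gap_score for each further one; our convention charges
    # open + extend for a length-1 gap.
    aligner.open_gap_score = scoring.gap_open + scoring.gap_extend
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def align_pair(a: str, b: str, scoring: AlignScoring = DEFAULT_SCORING) -> PairwiseAlignment:
    """Optimal global alignment of two concrete sequences."""
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = _make_aligner(scoring, "global")
    aln = next(iter(aligner.align(a.upper(), b.upper())))
    return PairwiseAlignment(aligned_query=aln[0], aligned_subject=aln[1], score=aln.score)


def chunk_region(
    region: SeqRecord,
    min_len: int = 100_000,
    max_len: int = 200_000,
    overlap: int = 500,
) -> list[tuple[int, SeqRecord]]:
    """Tile a region into near-equal chunks within [min_len, max_len].

    Consecutive chunks share exactly ``overlap`` bp so that no candidate
    segment is split across a boundary; the final chunk may be shorter.
    Returns (region-relative 0-based offset, chunk record) tuples.
    """
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    if overlap >= min_len:
        raise ValueError("overlap must be smaller than min_len")
    L = len(region.seq)
    if L <= max_len:
        return [(0, SeqRecord(id=f"{region.id}|chunk0", seq=region.seq))]
    target = min(max(150_000, min_len), max_len)
    n = max(1, round((L - overlap) / (target - overlap)))
    while True:
        chunk_len = -(-(L + (n - 1) * overlap) // n)  # ceil division
        if chunk_len > max_len:
            n += 1
        elif chunk_len < min_len and n > 1:
            n -= 1
        else:
            break
    step = chunk_len - overlap
    chunks = []
    i = 0
    offset = 0
    while offset < L:
        end = min(offset + chunk_len, L)
        chunks.append((offset, SeqRecord(id=f"{region.id}|chunk{i}", seq=region.seq[offset:end])))
        if end == L:
            break
        offset += step
        i += 1
    return chunks


def _cluster_seeds(
    seeds: Sequence[tuple[int, int]], band: int = 16, max_gap: int = 200
) -> list[list[tuple[int, int]]]:
    """Greedy clustering of (qpos, spos) seed hits by diagonal and proximity."""
    clusters: list[dict] = []
    for qpos, spos in sorted(seeds, key=lambda t: (t[0] - t[1], t[0])):
        diag = qpos - spos
        placed = False
        for cl in clusters:
            if abs(diag - cl["diag"]) <= band and abs(qpos - cl["qmax"]) <= max_gap:
                cl["seeds"].append((qpos, spos))
                cl["qmax"] = max(cl["qmax"], qpos)
                cl["diag"] = (cl["diag"] * (len(cl["seeds"]) - 1) + diag) / len(cl["seeds"])
                placed = True
                break
        if not placed:
            clusters.append({"seeds": [(qpos, spos)], "diag": float(diag), "qmax": qpos})
    return [cl["seeds"] for cl in clusters]


def _local_alignment_region(
    qwin: str, swin: str, scoring: AlignScoring
) -> Optional[tuple[PairwiseAlignment, int, int, int, int]]:
    """Best local alignment of two windows; returns (alignment, q0, q1, s0, s1)."""
    aligner = _make_aligner(scoring, "local")
    alns = aligner.align(qwin, swin)
    try:
        aln = next(iter(alns))
    except StopIteration:
        return None
    blocks_q, blocks_s = aln.aligned
    if len(blocks_q) == 0:
        return None
    q0, q1 = int(blocks_q[0][0]), int(blocks_q[-1][1])
    s0, s1 = int(blocks_s[0][0]), int(blocks_s[-1][1])
    pw = PairwiseAlignment(aligned_query=aln[0], aligned_subject=aln[1], score=aln.score)
    return pw, q0, q1, s0, s1


def find_homologous_pairs(
    query: SeqRecord,
    subjects: Iterable[SeqRecord],
    min_identity: float = 0.85,
    delta_range: tuple[int, int] = (1, 10),
    min_len: int = 80,
    k: int = 15,
    scoring: AlignScoring = DEFAULT_SCORING,
    pad: int = 60,
) -> list[HomologyPair]:
    """Find segments of ``subjects`` homologous to segments of ``query`` whose
    lengths differ by a net ``delta_range`` bp.

    Both subject strands are searched; self-hits (identical coordinates on
    the same sequence) are excluded.  Pairs are sorted by descending score,
    ties broken by smaller |delta| then leftmost query coordinate.
    """
    lo, hi = delta_range
    if lo < 1:
        raise ValueError("delta lower bound must be >= 1 (delta 0 is unresolvable)")
    if min_len < 50:
        raise ValueError("min_len must be >= 50")
    qseq = query.seq
    index: dict[str, list[int]] = {}
    for i in range(len(qseq) - k + 1):
        index.setdefault(qseq[i : i + k], []).append(i)

    pairs: list[HomologyPair] = []
    for rec in subjects:
        for strand in ("+", "-"):
            sseq = rec.seq if strand == "+" else revcomp(rec.seq)
            seeds = []
            for j in range(len(sseq) - k + 1):
                kmer = sseq[j : j + k]
                for i in index.get(kmer, ()):
                    seeds.append((i, j))
            if not seeds:
                continue
            for cluster in _cluster_seeds(seeds, band=max(16, hi + 6)):
                qlo = max(0, min(q for q, _ in cluster) - pad)
                qhi = min(len(qseq), max(q for q, _ in cluster) + k + pad)
                slo = max(0, min(s for _, s in cluster) - pad)
                shi = min(len(sseq), max(s for _, s in cluster) + k + pad)
                res = _local_alignment_region(qseq[qlo:qhi], sseq[slo:shi], scoring)
                if res is None:
                    continue
                aln, q0, q1, s0, s1 = res
                if len(aln) < min_len or aln.identity < min_identity:
                    continue
                delta = aln.delta
                if not (lo <= abs(delta) <= hi):
                    continue
                qa, qb = qlo + q0, qlo + q1  # 0-based half-open on query
                if strand == "+":
                    sa, sb = slo + s0, slo + s1
                else:
                    sa, sb = len(sseq) - (slo + s1), len(sseq) - (slo + s0)
                query_iv = GenomicInterval(query.id, qa + 1, qb)
                subject_iv = GenomicInterval(rec.id, sa + 1, sb, strand=strand)
                if rec.id == query.id and (qa + 1, qb) == (sa + 1, sb):
                    continue  # self-hit
                pairs.append(
                    HomologyPair(
                        query_iv=query_iv,
                        subject_iv=subject_iv,
                        identity=aln.identity,
                        delta=delta,
                        alignment=aln,
                        score=aln.score,
                        query_seq=qseq[qa:qb],
                        subject_seq=sseq[slo + s0 : slo + s1],
                    )
                )

    pairs = _dedupe_pairs(pairs)
    pairs.sort(key=lambda p: (-p.score, abs(p.delta), p.query_iv.start))
    return pairs


def _dedupe_pairs(pairs: list[HomologyPair]) -> list[HomologyPair]:
    """Keep the best-scoring pair among mutually overlapping candidates."""
    kept: list[HomologyPair] = []
    for p in sorted(pairs, key=lambda p: -p.score):
        dup = False
        for q in kept:
            if (
                p.query_iv.overlaps(q.query_iv)
                and p.subject_iv.chrom == q.subject_iv.chrom
                and p.subject_iv.start <= q.subject_iv.end
                and p.subject_iv.end >= q.subject_iv.start
            ):
                dup = True
                break
        if not dup:
            kept.append(p)
    return kept


def pairs_to_tsv(pairs: Iterable[HomologyPair]) -> str:
    """Serialize pairs as TSV (one line per pair, header included)."""
    lines = [
        "query_chrom\tquery_start\tquery_end\tsubject_chrom\tsubject_start"
        "\tsubject_end\tsubject_strand\tidentity\tdelta\tscore"
    ]
    for p in pairs:
        lines.append(
            f"{p.query_iv.chrom}\t{p.query_iv.start}\t{p.query_iv.end}"
            f"\t{p.subject_iv.chrom}\t{p.subject_iv.start}\t{p.subject_iv.end}"
            f"\t{p.subject_iv.strand}\t{p.identity:.4f}\t{p.delta}\t{p.score:g}"
        )
    return "\n".join(lines) + "\n"
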