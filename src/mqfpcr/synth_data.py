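"""Deterministic generators of test substrate for the whole pipeline.

Two generators:

* :func:`make_paralog_genome` builds a toy two-chromosome genome carrying a
  planted homologous segment pair: identical primer-site stretches at both
  segment ends, point substitutions tuned to a target identity, and one net
  indel of a chosen length between the sites -- the geometry a dosage assay
  needs (two co-amplifiable segments resolvable by size).

* :func:`simulate_cohort` emulates the fluorescent peak-area readout of an
  assay on a cohort: per sample, each amplicon's area is proportional to
  its template copy number times a multiplicative lognormal noise term
  (mean 1, chosen coefficient of variation), optionally skewed by an
  amplification-efficiency bias on the test product; one reference-pool
  sample with population-mean copy numbers and no noise is always included.

All randomness flows from the single seed in the spec, so every artifact
is reproducible byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .insilico_pcr import find_binding_sites
from .primer_design import CandidateAssay
from .seqcore import GenomicInterval, Primer, SeqRecord

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ParalogGenomeSpec:
    """Geometry of a planted homologous segment pair."""

    segment_length: int = 400      # length of the test-side segment (bp)
    identity: float = 0.95         # target alignment identity
    delta: int = 2                 # net indel, test minus control segment (bp)
    flank_length: int = 300        # random flank on each side of each segment
    primer_site_length: int = 20   # exactly conserved stretch at each segment end
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.delta <= 10):
            raise ValueError("delta must lie in [0, 10]")
        if not (0.7 < self.identity <= 1.0):
            raise ValueError("identity must lie in (0.7, 1]")
        if not (15 <= self.primer_site_length <= 25):
            raise ValueError("primer_site_length must lie in [15, 25]")
        if self.segment_length < 2 * self.primer_site_length + self.delta + 20:
            raise ValueError("segment_length too short for sites + indel")


@dataclass
class PlantedTruth:
    """Ground truth accompanying a generated paralog genome."""

    query_iv: GenomicInterval        # test segment on chromA
    subject_iv: GenomicInterval      # control segment on chromB
    delta: int
    fwd_site: str                    # exactly conserved 5' stretch (both segments)
    rev_site: str                    # exactly conserved 3' stretch (both segments)
    n_substitutions: int
    product_sizes: tuple[int, int]   # (test, control) site-to-site span


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def make_paralog_genome(
    spec: ParalogGenomeSpec,
) -> tuple[list[SeqRecord], PlantedTruth]:
    """Generate a two-chromosome genome with one planted homologous pair.

    chromA carries the test segment; chromB carries a copy mutated to the
    target identity with one deletion of ``delta`` bp placed midway between
    the two exactly conserved primer-site stretches.  Flanks are random and
    verified free of additional primer-site matches.  Raises when the
    identity/delta combination cannot fit in ``segment_length``.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.segment_length
    site = spec.primer_site_length

    n_sub = round((1 - spec.identity) * L)
    # substitutions live strictly between the primer sites, clear of the indel
    del_start = L // 2 - spec.delta // 2
    protected = set(range(site + 3)) | set(range(L - site - 3, L))
    protected |= set(range(del_start - 2, del_start + spec.delta + 2))
    candidates = [i for i in range(L) if i not in protected]
    if n_sub > len(candidates):
        raise ValueError(
            f"identity {spec.identity} needs {n_sub} substitutions but only "
            f"{len(candidates)} positions are free of sites/indel"
        )

    for attempt in range(20):
        seg_a = _random_seq(rng, L)
        fwd_site = seg_a[:site]
        rev_site = seg_a[-site:]
        seg_b_list = list(seg_a)
        sub_pos = rng.choice(len(candidates), size=n_sub, replace=False)
        for i in sub_pos:
            pos = candidates[i]
            alternatives = [b for b in "ACGT" if b != seg_a[pos]]
            seg_b_list[pos] = alternatives[rng.integers(0, 3)]
        del seg_b_list[del_start : del_start + spec.delta]
        seg_b = "".join(seg_b_list)

        chrom_a = SeqRecord(
            id="chromA",
            seq=_random_seq(rng, spec.flank_length) + seg_a + _random_seq(rng, spec.flank_length),
        )
        chrom_b = SeqRecord(
            id="chromB",
            seq=_random_seq(rng, spec.flank_length) + seg_b + _random_seq(rng, spec.flank_length),
        )
        if _sites_unique(fwd_site, rev_site, [chrom_a, chrom_b]):
            break
    else:
        raise RuntimeError("could not place primer sites without spurious matches")

    truth = PlantedTruth(
        query_iv=GenomicInterval("chromA", spec.flank_length + 1, spec.flank_length + L),
        subject_iv=GenomicInterval("chromB", spec.flank_length + 1, spec.flank_length + len(seg_b)),
        delta=spec.delta,
        fwd_site=fwd_site,
        rev_site=rev_site,
        n_substitutions=n_sub,
        product_sizes=(L, L - spec.delta),
    )
    return [chrom_a, chrom_b], truth


def _sites_unique(fwd_site: str, rev_site: str, genome: list[SeqRecord]) -> bool:
    """True iff each planted site binds exactly once per chromosome."""
    for site_seq in (fwd_site, rev_site):
        probe = Primer("site_probe", site_seq, role="forward")
        for rec in genome:
            if len(find_binding_sites(probe, rec, max_mismatch=2)) != 1:
                return False
    return True


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSpec:
    """Copy-number dosage and noise model for a simulated cohort.

    ``case_test_copies`` / ``control_test_copies`` are template copy
    numbers of the test amplicon in affected and normal samples (e.g.
    1 vs 2 for a hemizygous deletion, 3 vs 2 for an autosomal duplication,
    2 vs 1 for a duplicated X in males); the control amplicon is fixed at
    ``control_amplicon_copies`` (2) for everyone.  ``efficiency_bias``
    multiplies the test amplicon's yield, emulating uneven amplification
    efficiency between products of different size; the reference-pool
    normalization is what cancels it.  ``cv`` is the coefficient of
    variation of the per-peak multiplicative lognormal noise.
    """

    n_controls: int = 100
    n_cases: int = 14
    case_test_copies: float = 1.0
    control_test_copies: float = 2.0
    control_amplicon_copies: float = 2.0
    efficiency_bias: float = 1.0
    cv: float = 0.05
    seed: int = 0
    reference_id: str = "REFPOOL"

    def __post_init__(self) -> None:
        if self.case_test_copies < 0 or self.control_test_copies < 0:
            raise ValueError("copy numbers must be >= 0")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.efficiency_bias <= 0:
            raise ValueError("efficiency_bias must be positive")


#: Fluorescence area contributed by one template copy at nominal efficiency.
AREA_PER_COPY = 5000.0
#: Height is a fixed fraction of area for a well-formed capillary peak.
_HEIGHT_PER_AREA = 0.12
#: Maximum sizing jitter applied to simulated peak positions (bp).
SIZE_JITTER = 0.3


def _lognormal_eps(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Multiplicative noise, lognormal with mean exactly 1 and the given CV."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=size)


def simulate_cohort(
    assay: CandidateAssay, spec: CohortSpec
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a fluorescent peak table for a cohort run with ``assay``.

    Returns (peaks, labels): ``peaks`` has columns Sample, Dye, Size,
    Height, Area (two rows per sample, test and control peak); ``labels``
    has sample_id, group (reference/control/case) and test_copies.
    Identical spec (same seed) reproduces identical tables.
    """
    rng = np.random.default_rng(spec.seed)
    test_size = assay.test_amplicon.size_tailed
    control_size = assay.control_amplicon.size_tailed

    samples: list[tuple[str, str, float]] = [(spec.reference_id, "reference", spec.control_test_copies)]
    samples += [
        (f"CTRL{i + 1:04d}", "control", spec.control_test_copies)
        for i in range(spec.n_controls)
    ]
    samples += [
        (f"CASE{i + 1:04d}", "case", spec.case_test_copies)
        for i in range(spec.n_cases)
    ]

    n = len(samples)
    eps_test = _lognormal_eps(rng, spec.cv, n)
    eps_ctrl = _lognormal_eps(rng, spec.cv, n)
    jit_test = rng.uniform(-SIZE_JITTER, SIZE_JITTER, size=n)
    jit_ctrl = rng.uniform(-SIZE_JITTER, SIZE_JITTER, size=n)
    eps_test[0] = eps_ctrl[0] = 1.0  # the reference pool defines the baseline

    rows = []
    label_rows = []
    for i, (sample_id, group, test_copies) in enumerate(samples):
        test_area = AREA_PER_COPY * test_copies * spec.efficiency_bias * eps_test[i]
        ctrl_area = AREA_PER_COPY * spec.control_amplicon_copies * eps_ctrl[i]
        rows.append(
            (sample_id, "NED", round(test_size + jit_test[i], 2),
             round(test_area * _HEIGHT_PER_AREA, 1), round(test_area, 1))
        )
        rows.append(
            (sample_id, "NED", round(control_size + jit_ctrl[i], 2),
             round(ctrl_area * _HEIGHT_PER_AREA, 1), round(ctrl_area, 1))
        )
        label_rows.append((sample_id, group, test_copies))

    peaks = pd.DataFrame(rows, columns=["Sample", "Dye", "Size", "Height", "Area"])
    labels = pd.DataFrame(label_rows, columns=["sample_id", "group", "test_copies"])
    return peaks, labels


def peaks_to_tsv(peaks: pd.DataFrame, header_lines: Optional[list[str]] = None) -> str:
    """Serialize a simulated peak table as TSV with optional ``#`` provenance lines."""
    prefix = "".join(f"# {line}\n" for line in (header_lines or []))
    return prefix + peaks.to_csv(sep="\t", index=False)
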