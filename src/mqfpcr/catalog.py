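"""Catalog of validated MQF-PCR assays (GRCh37 coordinates).

Four single-primer-pair dosage assays covering two microdeletion syndromes
(Williams-Beuren at 7q11.23, Velocardiofacial/22q11.2) and two
microduplication syndromes (Lubs/MECP2 at Xq28, NF1 at 17q11.2).  Each
assay co-amplifies a segment of the disease critical region (test) and a
paralogous segment elsewhere in the genome (control); the two products
differ by a few bp and are resolved by capillary electrophoresis.

Fragment sizes are the electrophoretic (tailed) sizes of the labelled
products.  Note that these sizes and the genomic coordinate spans cannot
be reconciled exactly by tail arithmetic alone (sizing calibration and
3' adenylation introduce about +-1 bp of ambiguity); both are kept as
reported, with the fragment sizes treated as the electrophoretic truth.
"""

from __future__ import annotations

from .primer_design import (
    M13_40_TAIL,
    PIG_TAIL,
    CandidateAssay,
    PlannedAmplicon,
)
from .seqcore import GenomicInterval, Primer


def _assay(
    name: str,
    fwd_core: str,
    rev_core: str,
    test_loc: tuple[str, int, int],
    test_size: int,
    control_loc: tuple[str, int, int],
    control_size: int,
) -> CandidateAssay:
    return CandidateAssay(
        name=name,
        forward=Primer(f"{name}-MQF-F", fwd_core, tail=M13_40_TAIL, role="forward"),
        reverse=Primer(f"{name}-MQF-R", rev_core, tail=PIG_TAIL, role="reverse"),
        amplicons=[
            PlannedAmplicon(
                interval=GenomicInterval(*test_loc),
                size_untailed=test_size - 24,
                size_tailed=test_size,
                role="test",
            ),
            PlannedAmplicon(
                interval=GenomicInterval(*control_loc),
                size_untailed=control_size - 24,
                size_tailed=control_size,
                role="control",
            ),
        ],
        delta_size=test_size - control_size,
    )


#: Williams-Beuren syndrome (7q11.23 deletion); control paralog on 18p11.32.
WBS = _assay(
    "WBS",
    fwd_core="TGGGAGGGCCATTTTGTCAC",
    rev_core="TTATTGTTCTGCRTCTGGG",
    test_loc=("chr7", 73_536_635, 73_536_831),
    test_size=218,
    control_loc=("chr18", 675_837, 676_031),
    control_size=214,
)

#: Velocardiofacial / 22q11.2 deletion syndrome; control paralog on 3p11.1.
VCF = _assay(
    "VCF",
    fwd_core="GTATTTGGAAGWGTTTCTGTATAGA",
    rev_core="GAGAACTGGGTTTACCTGAC",
    test_loc=("chr22", 19_618_131, 19_618_209),
    test_size=99,
    control_loc=("chr3", 88_205_817, 88_205_900),
    control_size=104,
)

#: Lubs syndrome (MECP2 duplication, Xq28); control paralog on 5p13.3.
LUBS = _assay(
    "LUBS",
    fwd_core="TGAAACCTGACTTGCTTCT",
    rev_core="GCACTGATTGTGGCAGAG",
    test_loc=("chrX", 153_276_119, 153_276_295),
    test_size=197,
    control_loc=("chr5", 32_649_017, 32_649_192),
    control_size=198,
)

#: 17q11.2 microduplication (NF1); control paralog on 13q12.11.
NF1 = _assay(
    "NF1",
    fwd_core="TGTTACCTGGTGTCTAGAGC",
    rev_core="GCCCCTTAGACCATAATG",
    test_loc=("chr17", 29_468_898, 29_469_033),
    test_size=159,
    control_loc=("chr13", 19_673_801, 19_673_931),
    control_size=153,
)

ASSAYS: dict[str, CandidateAssay] = {"WBS": WBS, "VCF": VCF, "LUBS": LUBS, "NF1": NF1}

#: Direction of the dosage change each assay detects.
DIRECTIONS: dict[str, str] = {
    "WBS": "deletion",
    "VCF": "deletion",
    "LUBS": "duplication",
    "NF1": "duplication",
}
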