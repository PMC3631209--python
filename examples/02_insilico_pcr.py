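"""Degenerate-aware in-silico PCR with a published primer pair.

The WBS assay's reverse primer carries an R (A/G) base, letting one primer
bind both the 7q11.23 segment and its chr18 paralog.  This script embeds
both concrete variants of the binding site in synthetic templates and shows
that the single degenerate primer finds each of them, then enumerates the
products of a toy two-template PCR.
"""

import numpy as np

from mqfpcr import catalog, enumerate_amplicons, find_binding_sites, revcomp
from mqfpcr.seqcore import SeqRecord, expand_degenerate

rng = np.random.default_rng(0)
flank = lambda n: "".join(rng.choice(list("ACGT"), n))  # noqa: E731

rev = catalog.WBS.reverse
print(f"WBS reverse primer core: {rev.core} (degenerate base R = A/G)")
for variant in expand_degenerate(rev.core):
    template = SeqRecord(id="t", seq=flank(80) + variant + flank(80))
    sites = find_binding_sites(rev, template, max_mismatch=0)
    print(f"  embedding {variant}: {len(sites)} site(s), "
          f"strand {sites[0].strand}, footprint {sites[0].start}-{sites[0].end}")

# a toy pair of templates mimicking the test/control geometry: same primer
# sites, inner spacers differing by 4 bp
fwd = catalog.WBS.forward
inner = flank(140)
test_t = SeqRecord(id="chr7_like", seq=flank(30) + fwd.core + inner + revcomp(expand_degenerate(rev.core)[0]) + flank(30))
ctrl_t = SeqRecord(id="chr18_like", seq=flank(30) + fwd.core + inner[4:] + revcomp(expand_degenerate(rev.core)[1]) + flank(30))
amps = enumerate_amplicons(fwd, rev, [test_t, ctrl_t])
for a in amps:
    print(f"product on {a.chrom}: {a.size_untailed} bp genomic, "
          f"{a.size_tailed} bp with M13-40 + PIG tails")
sizes = sorted(a.size_tailed for a in amps)
print(f"size difference: {sizes[1] - sizes[0]} bp -> resolvable on a capillary")
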