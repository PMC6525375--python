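"""Collapse an alignment into haplotypes and summarise genetic variability.

Simulates a small study-shaped mtDNA dataset, then prints the per-region and
total diversity rows: sample size N, haplotype number Nh, polymorphic sites
Nps, haplotype diversity h (probability two random sequences differ),
nucleotide diversity pi (per-site), and K (mean pairwise differences).
"""

import mitopop as mp

aln, hier, _ = mp.generate_fixture_study(seed=1)
table = mp.collapse_haplotypes(aln, hier)
sites = aln.included_sites()

summ = mp.site_summary(aln)
print(f"{aln.n} sequences x {aln.length} bp; {summ.n_variable} variable sites "
      f"({summ.n_parsimony_informative} parsimony-informative, "
      f"{summ.n_singleton} singletons)")

rows = mp.diversity_report(table, hier, sites, len(sites))
print(f"{'group':<28}{'N':>5}{'Nh':>5}{'Nps':>5}{'h':>10}{'pi':>10}{'K':>8}")
for r in rows:
    if r.level in ("region", "sub_region", "total"):
        print(f"{r.group:<28}{r.N:>5}{r.Nh:>5}{r.Nps:>5}"
              f"{r.h:>10.3f}{r.pi:>10.4f}{r.K:>8.3f}")
print("\nLow pi with moderate h is the classic signature of a recently "
      "expanded mtDNA pool: many young haplotypes, few differences.")
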