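"""Context-stratified divergence statistics on a simulated species pair.

Every compared column is labeled by region (5'UTR / CDS / 3'UTR), CpG
context (CG dinucleotide in either member) and codon degeneracy class;
divergence per stratum is substitutions over base pairs compared.  The fold
ratios quantify CpG hypermutability and coding constraint.
"""

from orthodiv import SimulationConfig, fold_ratios, simulate_transcriptomes
from orthodiv.divergence import DivergenceTable
from orthodiv.experiments import site_table

world = simulate_transcriptomes(SimulationConfig(n_transcripts=60, seed=42))
sites = site_table(world)
table = DivergenceTable.from_sites(sites)

print(table.rows[["group", "stratum", "pct_diff", "se", "compared_kb",
                  "ts_tv"]].round(3).to_string(index=False))
print()
for name, value in fold_ratios(table).items():
    print(f"{name}: {value:.2f}")
# CDS divergence sits well below the UTRs (purifying selection), the 4d
# stratum approaches the neutral UTR level, and every CpG stratum exceeds
# its non-CpG counterpart by several fold.
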