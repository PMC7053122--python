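"""Contiguity metrics for a synthetic assembly with a known answer.

Builds a six-scaffold assembly with prescribed lengths and one real gap,
then computes scaffold- and contig-basis statistics and the NG(X) curve
against an estimated genome size of 0.4 Mb.
"""

from asmqc import assembly_metrics, ng_curve
from asmqc.fixtures import FixtureSpec, generate_assembly

spec = FixtureSpec(
    seed=1,
    lengths=[80_000, 70_000, 50_000, 40_000, 30_000, 20_000],
    gap_runs={0: [(10_000, 25)]},  # one 25 bp N run splits scaffold 1
)
records, truth = generate_assembly(spec, estimated_genome_size=400_000)

scaffold, contig = assembly_metrics(records, estimated_genome_size=400_000, label="demo")
print(f"scaffolds: {scaffold.n_scaffolds}  contigs: {scaffold.n_contigs}")
print(f"total bases: {scaffold.total_bases:,}  %N: {scaffold.n_percent:.4f}")
print(f"scaffold N50/L50: {scaffold.n50:,} / {scaffold.l50}")
print(f"NG50/LG50 (G = 400 kb): {scaffold.ng50:,} / {scaffold.lg50}")
print(f"contig N50: {contig.n50:,}")

curve = ng_curve([len(r) for r in records], 400_000, "demo")
defined = sum(v is not None for v in curve.values)
print(f"NG(X) defined up to threshold {defined}% (assembly is {scaffold.total_bases/400_000:.0%} of G)")

# N50 is the length of the shortest scaffold in the smallest set of longest
# scaffolds covering half the assembly; NG50 uses half the genome size
# instead, so it is smaller whenever the assembly undershoots G.
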