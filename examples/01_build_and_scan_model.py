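"""Build an operator-site model and scan a genome for candidates.

Samples 22 aligned ARG-box-like sites from a palindromic consensus,
builds a symmetrized information model, and scans a 100-kb GC-rich
background genome with 50 planted sites at a 5-bit threshold.
"""

from argbox import build_site_matrix, gen_genome, gen_sites, rsequence, scan

sites = gen_sites(n_sites=22, mutation_rate=0.05, seed=11)
model = build_site_matrix(sites, symmetrize=True, pseudocount=0.5)
print(f"model: {model.width} nt wide, {model.n_sites} effective sites "
      f"(complements appended)")
print(f"R_sequence = {rsequence(model, sites):.1f} bits "
      "(mean information of a training site)")

genome, truth = gen_genome(100_000, gc=0.72, sites=sites, n_plant=50, seed=12)
hits = scan(model, genome, threshold=5.0, dedupe=True)
recovered = sum(t in {h.offset for h in hits} for t in truth["start"])
print(f"{len(hits)} windows scored >= 5 bits; "
      f"{recovered}/{len(truth)} planted sites recovered at exact offsets")
print("top hit:", max(hits, key=lambda h: h.ri))
# A high R_sequence (~32 bits here) means single sites are easily separable
# from a GC-0.72 background; hits above 5 bits that are not planted are
# either chance background matches or mutated-site look-alikes.
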