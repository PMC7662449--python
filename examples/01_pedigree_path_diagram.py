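"""Evaluate a two-layer breed pedigree as a Wright path diagram.

Brangus is a stabilized composite of 5/8 Angus and 3/8 Brahman; a
first-generation Ultrablack is a 50/50 Brangus x Angus cross. Encoding
the pedigree as a path diagram (squared edge coefficients = the
pedigree fractions) and summing squared direct and compound path
coefficients recovers the pedigree-expected genomic shares.
"""

from gbckit import determination_from_diagram, trace_wright_paths, ultrablack_diagram

diagram = ultrablack_diagram()  # p_CA^2=0.625, p_CB^2=0.375, p_DA^2=p_DC^2=0.5

for source in ("Angus", "Brahman"):
    paths = trace_wright_paths(diagram, source, "Ultrablack")
    det = determination_from_diagram(diagram, source, "Ultrablack")
    print(f"{source} -> Ultrablack")
    for p in paths:
        print(f"  path {p!r}: coefficient {p.coefficient:.6f}")
    print(f"  determination = {det:.4f}  ({det:.2%} of the Ultrablack genome)")

# The printed determinations, 0.8125 and 0.1875, match the pedigree
# expectation for an animal that is 1/2 Angus + 1/2 (5/8 Angus, 3/8 Brahman).
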