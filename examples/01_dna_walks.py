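"""DNA-walk encodings: one sequence, three ±1 rules.

Each base maps to +1 or −1 under a biochemical dichotomy; the running sum
is a one-dimensional walk whose endpoint counts the base imbalance of the
rule. The RY endpoint ties directly to the Chargaff (pyrimidine/purine)
ratio: ξ = (M − X_M) / (M + X_M).
"""

from dnawalk import NucleotideSequence, map_steps, summarize, walk

seq = NucleotideSequence(id="demo", symbols="ATGGCCTAACGTTAGCCTAA")
print(f"sequence {seq.id}: {seq.symbols}  (M = {seq.M})")

for rule, meaning in [
    ("RY", "purine {A,G} vs pyrimidine {C,T}"),
    ("SW", "strong bond {C,G} vs weak bond {A,T}"),
    ("KM", "amino {A,C} vs keto {G,T}"),
]:
    path = walk(map_steps(seq, rule))
    print(f"{rule} ({meaning}): endpoint X_M = {path.final:+d}")

comp = summarize(seq)
x_m = walk(map_steps(seq, "RY")).final
print(f"\nChargaff ratio ξ = {comp.xi:.4f}")
print(f"from RY endpoint: (M − X_M)/(M + X_M) = {(seq.M - x_m) / (seq.M + x_m):.4f}")
print("The two numbers agree because the RY endpoint is exactly the purine")
print("minus pyrimidine count; here it is 0, so the bases balance and ξ = 1.")
print("A purine-rich sequence would end above 0 and give ξ < 1.")
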