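"""Condition vectors: bit layouts, binning, and the size of condition space.

Reaction conditions for H₂-mediated reactions are encoded as multi-hot
bitstrings: one catalyst (one-hot), additive flags or compounds (multi-hot),
and binned temperature and pressure (one-hot each). This script builds the
two stock representations and shows why one of them admits exhaustive
ranking while the other cannot.
"""

from condvae import (ConditionRecord, bin_pressure, bin_temperature, decode,
                     encode, make_scheme, space_size)

scheme_s = make_scheme("S")
scheme_b = make_scheme("B")

print(f"scheme S: {scheme_s.n_bits} bits "
      f"({len(scheme_s.catalyst_vocab)} catalysts, "
      f"{len(scheme_s.additive_vocab)} additive flags, "
      f"{len(scheme_s.temp_bins)} T bins, {len(scheme_s.pressure_bins)} P bins)")
print(f"scheme B: {scheme_b.n_bits} bits "
      f"({len(scheme_b.catalyst_vocab)} catalysts, "
      f"{len(scheme_b.additive_vocab)} additive compounds)")

# temperature: <10 °C cooling, 10–40 ambient, >40 heating; pressure (B):
# <1 atm low, 1–3.5 ambient, 3.5–100 elevated, >100 high
for t in (5, 25, 60):
    print(f"  {t:>3} °C -> {scheme_b.temp_bins[bin_temperature(t, scheme_b)]}")
for p in (0.5, 2, 50, 200):
    print(f"  {p:>5} atm -> {scheme_b.pressure_bins[bin_pressure(p, scheme_b)]}")

record = ConditionRecord("Pd/C", frozenset({"acid"}), temperature=25.0,
                         pressure=1.0)
vec = encode(record, scheme_s)
print(f"\nencoded {record.catalyst} + acid at 25 °C / 1 atm -> "
      f"{sum(vec.bits)} bits set out of {len(vec.bits)}")
print("decoded back:", decode(vec))

n_s, n_b = space_size(scheme_s), space_size(scheme_b)
print(f"\nenumerable conditions, scheme S: {n_s}")
print(f"enumerable conditions, scheme B: {n_b:.1e}  (exact: {n_b})")
print("ranking by enumeration is feasible for S, impossible for B — the "
      "motivation for generating conditions instead of scoring all of them.")
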