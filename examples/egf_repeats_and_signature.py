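"""EGF-repeat calling and the calcium-binding digital signature.

Builds the canonical Notch1-like receptor (2,627 aa; 36 EGF repeats, 3
LNRs, 7 ANKs) and calls EGF-like repeats on its extracellular region by
their six-cysteine spacing grammar.  Each repeat contributes one bit to the
receptor's "digital format": 1 if its N-flank carries the calcium-binding
Asp/Asn consensus, 0 otherwise.
"""

from notchkit import digital_signature, find_egf_repeats, make_ancestor
from notchkit.simulate import canonical_roster

spec = next(s for s in canonical_roster() if s.name == "Notch1")
record, protein = make_ancestor(spec, seed=1)
start, end = protein.necd_span()
necd = record.residues[start:end]

repeats = find_egf_repeats(necd)
print(f"receptor length: {record.length} aa, NECD: {len(necd)} aa")
print(f"EGF-like repeats called: {len(repeats)}")
print(f"cysteines per repeat: {len(repeats[0].cysteine_positions)} "
      "(disulfide-paired 1-3, 2-4, 5-6)")

signature = digital_signature(necd)
print(f"digital signature (N->C): {signature}")
print(f"calcium-binding repeats: {signature.count('1')}/{len(signature)}")
assert signature == protein.cb_bits()  # matches the planted truth exactly
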