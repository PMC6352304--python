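"""Phase signals and the four descriptors on tiny hand-checkable sequences.

diff_p is order-sensitive: AAAGGG and AGAGAG share a base composition but
differ in adjacent-phase jumps.  tr_0 and tr_cg are dinucleotide fractions
read directly off the phase signal.
"""

from wgp import diff_p, phase_signal, tr_0, tr_cg

for seq in ("AAAGGG", "AGAGAG"):
    print(f"diff_p({seq}) = {diff_p(phase_signal(seq)):.2f}")

phase = phase_signal("CAGGCAG")
print(f"tr_0(CAGGCAG)  = {tr_0(phase):.4f}  (3 of 6 adjacent pairs cross zero)")
print(f"tr_cg(CAGGCAG) = {tr_cg(phase):.4f}  (2 of 6 pairs stay on C/G)")
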