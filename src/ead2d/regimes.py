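"""Reference operating points of the study's parameter space.

The two-parameter space is spanned by the G_CaL multiplier (x) and a
multiplier of one potassium-family conductance (y, G_Ks here).  These
module constants name the representative points used throughout the
package for the three emergent regimes.  The oscillatory point is the
one whose single-cell oscillation period equals the reported 166.7 ms
(6 Hz); the EAD / no-EAD points sit inside the corresponding single-cell
phase-diagram regions.
"""

BASELINE = {"mult_CaL": 1.0, "mult_Ks": 1.0}

#: single-cell EAD region; 2D P1 runs here break up at the waveback
EAD_POINT = {"mult_CaL": 5.0, "mult_Ks": 0.6}

#: oscillatory regime (single-cell oscillation at 6 Hz)
OSC_POINT = {"mult_CaL": 7.0, "mult_Ks": 0.45}

#: no-EAD (normal single-cell) region bordering the EAD region, where
#: P2-initiated spirals break up into Na-mediated fibrillation
SFB_POINT = {"mult_CaL": 2.0, "mult_Ks": 0.2}
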