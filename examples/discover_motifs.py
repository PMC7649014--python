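"""Conservation-window motif discovery on an EGF-repeat panel.

The panel aligns independently instantiated EGF-like units: grammar
positions (six cysteines, the Asn/Gly scaffold) are invariant, one aromatic
column alternates F/Y, everything else is random.  Discovery should return
exactly the two conserved EGF-internal motifs:

    Motif A: CXNGGXC
    Motif B: CXCXXG[FY]XG
"""

from notchkit import conservation_profile, discover_conserved_motifs
from notchkit.simulate import make_motif_panel

panel = make_motif_panel(n_rows=24, n_units=2, seed=0)
print(f"panel: {panel.n_rows} rows x {panel.n_columns} columns")

profile = conservation_profile(panel)
invariant = sum(stats.modal_freq == 1.0 for stats in profile.columns)
print(f"fully invariant columns: {invariant}")

patterns = discover_conserved_motifs(
    panel, invariant_tau=0.95, class_tau=0.95, min_len=7, max_wildcard_run=2
)
print("discovered patterns (X = any residue, [FY] = F or Y):")
for pattern in patterns:
    print(f"  {pattern.pattern}")
# Two copies of each motif appear because the panel carries two EGF units.
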