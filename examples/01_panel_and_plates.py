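"""Inspect the bundled KIR panel and plan a 384-well run.

The panel types 20 KIR markers in 10 triplex reactions (two targets plus the
STAT6 reference per well) in quadruplicate, so one fully typed sample costs
40 wells; with three controls on every plate, nine samples already need two
plates.
"""

from qkat import builtin_panel, plan_plates, reactions_per_sample

panel = builtin_panel()
print(f"panel: {panel.name}")
print(f"target markers: {len(panel.target_markers)}")
print(f"multiplex reactions: {len(panel.reactions)} (all triplex)")
print(f"primer pairs (incl. reference): {panel.n_primer_pairs}")
print(f"wells per fully typed sample: {reactions_per_sample(panel)}")

samples = [f"S{i}" for i in range(1, 10)]
controls = [(f"CTRL{i}", {}) for i in range(1, 4)]
layouts = plan_plates(panel, samples, controls)
print(f"\n{len(samples)} samples + {len(controls)} controls -> {len(layouts)} plates")
for layout in layouts:
    print(f"  {layout.plate_id}: {len(layout.wells)} occupied wells")
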