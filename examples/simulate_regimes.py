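"""Simulate root growth on ammonium and on nitrate and compare zonation.

Runs the multicellular model to its dynamic steady state under each
nitrogen regime and prints the elongation onsets, meristem size and
synchrony between the epidermis and cortex files — the regime contrasts
the model predicts (later, synchronized elongation and a larger meristem
on nitrate; earlier, asynchronous elongation on ammonium).
"""

from rootzone import ModelParameters, NitrogenRegime, run, summarize

params = ModelParameters()          # published posterior means

for name, N in (("ammonium", 0), ("nitrate", 1)):
    traj = run(params, NitrogenRegime.constant(N), horizon=400.0, seed=0)
    s = summarize(traj)
    print(f"--- {name} steady state (t = {traj.final.time:.0f}) ---")
    print(f"  elongation onset: epidermis cell {s.onset_index['epidermis']}, "
          f"cortex cell {s.onset_index['cortex']} "
          f"(synchrony index {s.synchrony_index})")
    print(f"  epidermal meristem: {s.meristem_cells['epidermis']} cells, "
          f"{s.meristem_size_um['epidermis']:.0f} µm from the QC")
    print(f"  division events so far: "
          f"{sum(traj.final.division_log.values())}")
    print(f"  auxin mass-balance residual: "
          f"{traj.final.ledger_residual():.1e} (should be ~1e-13)")

print("\nThe onset index is the first cell (counting from the quiescent "
      "centre) in the elongation zone; single-snapshot onsets fluctuate "
      "by about a cell around their stationary means (11 on ammonium, "
      "13 on nitrate in the epidermis).")
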