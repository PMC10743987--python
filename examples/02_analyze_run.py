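"""Full analysis of a single simulated run: segmentation, width-corrected
traces, and every per-beat transient / contraction / coupling parameter."""

from ecckymo import AnalysisConfig, SimCellParams, analyze_run, simulate_cell

params = SimCellParams(noise_sd=10.0, n_lines=3000, first_stim_ms=250.0,
                       seed=7)
kymo, truth = simulate_cell(params, cell_id="demo")

config = AnalysisConfig(search_start_ms=200.0)  # opens just before the stim
result = analyze_run(kymo, config)
print(f"run status: {result.status}, beats detected: {len(result.beats)}")

row = result.to_rows()[0]
tr = truth.beats.iloc[0]
print(f"\n{'parameter':34s} {'measured':>10s} {'true':>10s}")
for key in ("v_dff_max", "v_rise_time_ms", "v_tau90_ms",
            "ca_dff_max", "ca_rise_time_ms", "ca_tau50_ms", "ca_tau90_ms",
            "percent_shortening", "contraction_velocity_um_per_ms",
            "v_rise_to_ca_rise_ms", "v_peak_to_ca_peak_ms",
            "ca_peak_to_contraction_peak_ms", "v_peak_to_contraction_peak_ms"):
    print(f"{key:34s} {row[key]:10.3f} {tr[key]:10.3f}")

print("\nAmplitudes are dF/F0 ratios (dimensionless), times in ms, the "
      "velocity in um/ms.  The voltage Tau90 is the optical APD90.  At 5% "
      "photon noise the pipeline recovers times to a few line periods "
      "(1.24 ms each) and amplitudes to a few percent.")
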