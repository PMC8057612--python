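# Two-patient demonstration: calibrate each patient's hidden inflammation and
# microvessel levels against an observed follow-up NC growth, predict three
# years ahead, and emit trajectories, factor values and the severity score
# table.  Runs at reduced resolution (60x60) in well under five minutes.
output_dir: plaquesim_demo_out
resolution: 60
solver:
  t_end_months: 36.0
  snapshot_interval_months: 1.0
patients:
  - id: demo_stable
    ldl: 96.0
    hdl: 35.0
    wss: 132.0
    interval_months: 12.0
    nc_area_t1_um2: 600000.0
    observed_nc_growth: 1.05
    geometry:
      synthetic:
        n: 60
        lumen_radius_um: 550.0
        intima_a_um: 380.0
        intima_b_um: 150.0
        media_thickness_um: 300.0
        seed: 1
  - id: demo_unstable
    ldl: 151.0
    hdl: 21.0
    wss: 82.0
    interval_months: 12.0
    nc_area_t1_um2: 550000.0
    observed_nc_growth: 2.8
    geometry:
      synthetic:
        n: 60
        lumen_radius_um: 480.0
        intima_a_um: 420.0
        intima_b_um: 220.0
        media_thickness_um: 300.0
        seed: 2
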