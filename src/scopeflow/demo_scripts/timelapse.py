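# Cyclic timelapse-tiling experiment.
# Repeats the tile cycle n_lapses times: in each lapse every (unskipped)
# tile of the plan is visited and scanned, so tile dynamics can be
# followed over the whole extended field of view.
# Runs inside the acquisition unit's restricted namespace.

n_lapses = int(api.imcontrol.get_param("n_lapses", 10))
settle = float(api.imcontrol.get_param("settle_s", 1.0))
targets = api.imcontrol.get_tile_plan()

api.imcontrol.log_message(
    "timelapse: " + str(n_lapses) + " lapses over " + str(len(targets)) + " tiles"
)

for lapse in range(n_lapses):
    for t in targets:
        if t["skip"]:
            continue
        i = t["tile_index"][0]
        j = t["tile_index"][1]
        api.imcontrol.move_stage(x=t["x_um"], y=t["y_um"], z=t["z_um"])
        api.imcontrol.wait(settle)
        api.imcontrol.run_scan("lapse", tile=(i, j), lapse=lapse)
        api.imcontrol.wait_for_scan_end()

api.imcontrol.log_message("timelapse: done")
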