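# Selective tiling experiment.
# Visits every registered (unskipped) tile of the configured plan:
# move stage -> settle -> grid scan -> wait for the raw file on disk.
# Runs inside the acquisition unit's restricted namespace: only `api`
# (the exported control API) and basic builtins are available.

settle = float(api.imcontrol.get_param("settle_s", 1.0))
targets = api.imcontrol.get_tile_plan()

api.imcontrol.log_message("tiling: " + str(len(targets)) + " planned tiles")

for t in targets:
    i = t["tile_index"][0]
    j = t["tile_index"][1]
    if t["skip"]:
        api.imcontrol.log_message("tiling: skipping tile (" + str(i) + "," + str(j) + ")")
        continue
    api.imcontrol.move_stage(x=t["x_um"], y=t["y_um"], z=t["z_um"])
    api.imcontrol.wait(settle)
    api.imcontrol.run_scan("tile", tile=(i, j))
    api.imcontrol.wait_for_scan_end()

api.imcontrol.log_message("tiling: done")
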