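# Methods

## The synchronization model

scopeflow treats a shared folder tree as the only channel between the
three pipeline units. This is deliberate: a filesystem share is the one
transport every lab machine already has, it needs no broker or sockets,
and it makes every intermediate product inspectable. The cost is that
all coordination must be inferred from files, which drives three design
choices:

**Stability test.** A watcher must never process a file another machine
is still writing. A path is delivered only when its size and mtime are
unchanged across two consecutive polls; a Zarr store (a directory) is
judged on its recursive file count and total byte size instead. This
works on plain SMB/NFS shares with no writer cooperation, at the price
of one extra poll interval of latency. Writers inside scopeflow
additionally write to `*.part` names and rename on completion, so the
stability test is a second line of defense, not the only one.

**Exactly-once delivery.** Each watch session keeps an in-memory `seen`
set that only grows; a delivered path is never delivered again within a
session. Restarting a session reprocesses the folder (or ignores it:
by default files present at startup are marked seen without delivery,
i.e. the watcher watches "from now on"; `process_preexisting=True`
overrides this for reprocessing runs).

**Ordering.** Within a batch, paths are ordered lexicographically by
filename with mtime as tie-break — deterministic across platforms and
filesystems. Batches are processed in detection order, items within a
batch sequentially, which gives the FIFO behaviour the acquisition
queue relies on.

**Quiescence.** The units share no termination signal, so the
single-process demo infers completion: the submitted script has
finished, item counts are conserved across the pipeline (raw files =
reconstructions = registered layers), every queue is idle, and no unit
has seen activity for two poll intervals. A timeout turns a stalled
pipeline into a diagnostic error instead of a hang.

## The simulated instrument

The virtual microscope emulates a parallelized grid-scan
super-resolution acquisition at the level the framework needs — the
*shape and timing* of the data stream — not the optics:

- frame *k = ky·s + kx* (row-major over scan steps; the scan order is a
  package choice, made invertible rather than serpentine) reads
  `background + amplitude·S` at pixels with *x ≡ kx* (mod *p*) and
  *y ≡ ky* (mod *p*), and `background` elsewhere; *S* is the sample crop
  at the stage position (position snapped to the nearest pixel);
- with pitch equal to steps (default *p = s* = 18) the *s*² frames
  partition the FOV, so reconstruction is exactly invertible — the
  anchor for every end-to-end correctness test. *p > s* is allowed and
  leaves unseen pixels at background;
- per-frame duration is honoured as real elapsed time (`s²·period`), so
  pipeline latencies are meaningful;
- noise is per-pixel Poisson on the noiseless frame (shot-noise model),
  seeded per acquisition from (run seed, acquisition index) so a run is
  bit-reproducible regardless of thread timing;
- samples (`constant`, `spots`, `filaments`) are integer-valued
  intensity maps, so the uint16 camera quantization is lossless and
  noiseless identities hold exactly;
- optics blur (PSF convolution) exists as an option but is **off** by
  default: it would break exact invertibility and adds nothing to the
  framework contract under test.

What the simulator does *not* model — photoswitching kinetics,
out-of-focus background, stage drift and hysteresis, camera read noise,
3D — bounds what passing tests show: they validate the scheduling,
I/O, bookkeeping and reconstruction plumbing on realistic data shapes
and rates, not image quality on real specimens.

## Reconstruction

The default algorithm is focus reassignment: for frame *k*, each of its
focus positions receives the (2w+1)²-window sum of the
background-subtracted frame around that position. Parameters:

| parameter | default | meaning |
|---|---|---|
| `window_halfwidth_px` (w) | 0 | collection window per focus; must satisfy w < pitch/2 or neighboring windows overlap (rejected) |
| `background_mode` | `none` | `global_min` subtracts the stack minimum |
| `algorithm_id` | `focus_reassignment` | dispatch key; new stack→image transforms register via `register_algorithm` |

w = 0 with no background subtraction makes the stage an exact inverse
of the simulator's forward model; larger windows trade resolution for
photon collection on blurred/noisy data. Edge windows are clipped to
the frame. Outputs are 32-bit-float TIFF (metadata as ImageDescription
JSON) and single-scale OME-NGFF 0.4 Zarr, both written via temp-name +
rename. The NGFF metadata (y/x axes, µm scale from the acquisition
pixel size) is authored directly; one scale level is enough for tiles
of this size.

## Tiling geometry and conventions

Step between adjacent tiles is `fov·(1−overlap)`; the mosaic extent is
`n·fov − (n−1)·overlap·fov`. The canonical 5×5 grid of 38 µm tiles at
14 % overlap gives a 32.68 µm step and 168.72 µm span. Conventions,
fixed once and asserted in tests: stage x grows rightward and maps to
image columns, stage y grows downward and maps to rows; tile index
(i, j) is 0-based (column, row); visit order is row-major (serpentine
is a possible variant but not the default). Focus registration is a
headless table of (tile, z, skip) entries — the stand-in for
interactive per-tile focusing, needed because sample tilt makes z
differ per tile; automatic focus finding is explicitly not implemented.

## Mosaicking

Tiles are placed at nominal stage offsets,
`round((stage − min stage)/pixel_size)` px — the same rounding the
simulator applies when cropping, so noiseless simulate→reconstruct→
stitch is an exact identity. Cross-correlation refinement is
deliberately excluded; instead `overlap_consistency` reports the RMS
pixel difference over each overlapping pair's shared region: 0 for
perfectly consistent tiles, σ√2 for independent additive noise of
standard deviation σ, and strictly larger when a tile is misplaced —
a quantitative trigger for when true registration would be needed.
Blend modes: `overwrite`, `average` (default; per-pixel mean over
coverage, conserves constants and noiseless identities), `feather`
(distance-to-edge weighting for visibly seamless mosaics when tiles
disagree).

## Script sandbox

Experiment scripts are Python sources executed with only `api` (the
control API) and a short allow-list of builtins in scope — no import
machinery, no `open`. This mirrors an exported-API scripting surface
while keeping what a script can do auditable. Script failures are
caught, recorded as failed items, and never block the queue.

## Demo problem sizes

The bundled demos keep the canonical experiment *structure* — 5×5 tiles
at 14 % overlap (tiling), 2×2 tiles × 10 lapses with 1 s settle after
each move (timelapse), 18×18-step / 324-frame scans — at desk scale:
64×64 px tiles at 1 µm/px and a shortened frame period (0.5 ms in the
acceptance runs, configurable), chosen so a full three-unit run
completes in about a minute while exercising every code path at the
real experiments' counts and geometry. The synthetic specimen defaults
to `spots` (point-like emitters); `filaments` gives actin-like curves.

## Numerical and degenerate-input choices

- Raw stacks are uint16 (camera-like); reconstruction and mosaics are
  float64 internally, written as float32.
- Logger timestamps are ISO-8601 at millisecond precision; a parsed
  record whose latency disagrees with its timestamps by > 1.5 ms is a
  validation error naming the line.
- Zero-frame stacks are refused at write time; corrupt raw inputs yield
  a failed record and leave no partial outputs.
- Empty logs summarize as n = 0 with undefined statistics flagged as
  `None`; failed records are excluded from latency statistics but
  counted separately.
- Duplicate filenames (same tag, same stem, repeated log writes) are
  suffix-indexed, never overwritten.

## Known limitations

- The seen-set is per-session and in-memory: a crashed unit restarted
  with `process_preexisting=True` will reprocess everything; with the
  default it will process nothing old. Durable state was left out to
  keep the watcher dependency-free on shared filesystems.
- Polling latency floors the pipeline latency at ~2 poll intervals per
  hop (stability needs two sightings).
- Nominal-offset stitching assumes the stage is accurate to a pixel;
  the consistency metric detects, but does not correct, violations.
- One channel, 2D only; multi-channel/3D stacks and real device
  backends are out of scope.
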