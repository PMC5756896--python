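# songspace

Spatiotemporal analysis of acoustic interactions between territorial
songbirds recorded by multiple microphone arrays.

The pipeline starts from per-array direction-of-arrival (DOA) event streams
(one azimuth track per detected sound), and:

1. **Triangulates** 2D song locations from three arrays' bearings with
   spatial and temporal gating (`songspace.localization`);
2. assembles **per-individual song timelines** by attributing sources to
   song posts, and scores them against human annotations with
   duration-based TP/FP/TN/FN, accuracy and ROC rates
   (`songspace.timelines`);
3. quantifies **temporal overlap avoidance** (vacant/overlapped/solo
   decomposition, duty-cycle-preserving gap-shuffle randomization tests,
   asymmetric active-overlap test) and **directional influence** (plug-in
   transfer entropy on 0.5-s binarized series with surrogate testing),
   plus session-level bootstrap estimates (`songspace.interaction`);
4. provides a **synthetic soundscape generator** — birds at fixed posts with
   renewal song/gap processes, optional directed onset-suppression coupling,
   and a configurable observation-noise model producing realistic DOA events
   — so the entire pipeline is testable without field recordings
   (`songspace.synthetic`).

File I/O (geometry configs, DOA tables, annotations incl. Praat TextGrid
interval tiers, results tables) lives in `songspace.io_formats`; the
orchestrating CLI in `songspace.cli`.

## CLI

Each stage runs standalone on the previous stage's files:

```bash
songspace simulate  --config scenario.yml --out sim/
songspace localize  --geometry sim/geometry.yml --doa sim/doa_events.csv --out sources.csv
songspace timelines --sources sources.csv --posts posts.yml --window 0 600 --out timelines.csv
songspace evaluate  --localized timelines.csv --annotated sim/truth_timelines.csv
songspace interact  --timelines timelines.csv --windows bouts.csv \
                    --nrand 10000 --seed 7 --out tables/
```

or as one seeded, logged run that writes a manifest:

```bash
songspace run --config run.yml
```

See the docstrings of `songspace.synthetic.read_scenario` and
`songspace.io_formats.read_geometry` for the config schemas.  Times are
seconds from session start; intervals are half-open `[begin, end)`; the
internal azimuth convention is degrees counterclockwise from east (compass
azimuths are converted at the file boundary).

## Conventions and key defaults

| parameter | default | meaning |
|---|---|---|
| DOA frame step | 0.2 s | azimuth track sampling |
| spatial gate | 15 m | max pairwise distance of the 3 ray intersections |
| begin / end gates | 6.0 / 1.0 s | max pairwise event begin/end spreads |
| end correction | 0.6 s | subtracted from accepted source ends |
| analysis bin | 0.5 s | binarization for transfer entropy |
| TE histories k, l | 1, 1 | sink/source history lengths (bits, log base 2) |
| randomization / bootstrap draws | 10,000 | `n_rand`, `n_boot` |
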