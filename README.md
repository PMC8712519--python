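# usvpipe

Detection, filtering, classification and clustering of high-frequency and
ultrasonic vocalizations, built around the adult repertoire of the gray
mouse lemur (*Microcebus murinus*): Long whistle, Trill, Short whistle,
Tsak and Zip, all in the 5–50 kHz analysis band. The package is aimed at
bioacousticians who want an end-to-end, scriptable alternative to manual
sonogram screening — and a validation harness that quantifies exactly how
much an automated pass misses compared with reviewer-corrected scoring.

Real archive recordings are not required: a synthetic-scene generator
renders standardized files (one call type per file, units separated by 3 s
of white noise) and mixed "experimental" scenes with broadband noise
transients, each with exact ground truth, under four recording-quality
scenarios (good, clipped, low-amplitude, overlaid).

## The analysis

1. **Measurement core** (`spectral`) — short-time magnitude spectrograms
   (512-sample windows, 50 % overlap); per-frame *contours* (the frequency
   at maximum amplitude), cleaned by removing non-tonal frames, where
   tonality is `1 − spectral flatness`; acoustic features per contour:
   duration, peak-frequency statistics, bandwidth, least-squares slope,
   sinuosity, mean tonality and a syllable-count estimate.
2. **Detection** (`detect`) — three duration-stratified detectors (*long*:
   Long whistle & Trill; *short*: Short whistle & Tsak; *very short*: Zip)
   segment smoothed in-band energy above a noise-floor threshold, gated by
   tonality and by each profile's duration window.
3. **Cleanup** (`postfilter`) — a duplicate/fragment filter deletes
   short-profile boxes contained in longer-profile boxes and merges
   same-profile fragments; a random-forest denoiser rejects broadband
   noise detections from their acoustic features.
4. **Classification** (`classify`) — a seeded random forest labels each
   detection with a call type; confusion matrices report per-class
   precision (`tp / column sum`) and recall (`tp / row sum`).
5. **Clustering** (`cluster`) — k-means over standardized features with
   equal frequency/duration/contour group weights; the cluster count comes
   from the elbow of the inertia curve.
6. **Validation** (`evaluate`) — detections are matched to ground truth by
   temporal IoU; unmatched boxes fall into a false-positive taxonomy
   (*noise*, *call fragment*, *cluster* of series members, *overlaid*
   pair). Precision is `pr = tp / (tp + fp)` and recall `r = tp / tt`
   (*tt* = total true calls), scored both *automated* (no corrections) and
   *semi-automated* (fragments extended, clusters split, overlaid boxes
   credited to both calls — simulated reviewer edits).

## Worked example

```python
from usvpipe import (SceneSpec, build_standardized_file, compute_spectrogram,
                     default_profiles, detect, score_run)

scene = SceneSpec(kind="standardized", calls=(("tsak", 10),), seed=42)
clip, truth = build_standardized_file(scene)          # 10 series = 30 calls
sg = compute_spectrogram(clip)
boxes = detect(sg, default_profiles()["short"])
report = score_run([(boxes, truth)], mode="automated")
print(len(truth), len(boxes), round(report.precision, 2), round(report.recall, 2))
```

prints

```
30 30 1.0 1.0
```

— all 30 Tsak calls (10 series of three, intercall intervals < 200 ms) are
found by the short-duration detector with no false positives. Running the
same file through `default_profiles()["long"]` instead drops recall to
0.0: each Tsak is far below the long profile's 0.15 s duration gate, which
is precisely why detection is duration-stratified.

The same flow is available from the shell:

```bash
usvpipe synth standardized --call-type tsak 10 --seed 42 --out scene.wav
usvpipe detect scene.wav --profile short -o det.tsv
usvpipe evaluate --detections det.tsv --truth scene.tsv
```

`usvpipe model1|model2|model3 --seed N --out report.json` run the full
seeded studies: scenario robustness and cleanup steps, supervised
classification, and unsupervised clustering.

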