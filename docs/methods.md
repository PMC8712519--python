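# Methods

## Scope and design

`usvpipe` implements a complete detection → cleanup → classification →
clustering → validation chain for high-frequency/ultrasonic calls of the
gray mouse lemur repertoire, paired with a synthetic-scene generator that
stands in for archive recordings. The detector is a deterministic
spectrogram-energy/tonality segmenter, not a learned image detector: it is
desk-scale, needs no trained weights, and — by construction — exhibits the
same observable failure modes a box detector shows on this material (call
fragments, series members clustered into one box, trill syllables
re-reported as short calls, broadband noise detections). Those failure
modes are the point: the downstream filtering, reviewer-simulation and
scoring stages exist to measure and repair them.

## Synthetic vocalizations

Each call is a frequency-modulated sine with a seeded parametrization per
type. All frequency content lies in the 5–50 kHz analysis band; the
default sample rate is 192 kHz (any rate ≥ 100 kHz is accepted). The
per-type defaults are this package's own reconstruction of the repertoire
and are fully configurable (`CallTypeSpec`):

| type | tone duration | contour | fundamental | envelope | emission |
|---|---|---|---|---|---|
| Long whistle | 0.2–1.5 s | flat, drift ±2 kHz | 13–25 kHz | trapezoid | single |
| Trill | 0.08–0.18 s /syllable, 3–8 syllables, 10–40 ms gaps | sinusoidal FM, depth 2–6 kHz, rate 20–60 Hz | 15–28 kHz | trapezoid/syllable | single |
| Short whistle | 15–100 ms | shallow glide, 0–8 kHz down | 18–26 kHz | trapezoid | series of 3 |
| Tsak | 20–80 ms | steep down-sweep to 10–15 kHz | 30–40 kHz | trapezoid | series of 3 |
| Zip | 5–30 ms | down-sweep, 3–10 kHz drop | 20–30 kHz | hann | single |

Two modelling choices deserve emphasis:

* **The Short whistle–Zip continuum.** Short-whistle glides are drawn as
  `8 kHz × Beta(1, 5)`, i.e. mostly near-flat with a rare steep tail, and
  the duration range reaches down to 15 ms. The shortest, steepest Short
  whistles are therefore genuinely Zip-like — modelling the natural
  transitional forms between these types. This is what makes the
  rare-class experiment meaningful: a classifier facing hundreds of Short
  whistles and a handful of Zips *must* mislabel a few tail calls, exactly
  the regime in which a rare class keeps perfect recall while its
  precision collapses.
* **Trapezoid trill syllables.** With hann-enveloped syllables, the
  attenuated (low-amplitude) scenario shortens each syllable's detectable
  span enough that inter-syllable gaps exceed the long-profile fusing
  window; the trill then shatters into sub-gate fragments that no reviewer
  correction can recover (there is no box to extend). Trapezoid syllables
  keep the call connected while still degrading gracefully.

Series call types emit three calls per unit with intercall intervals drawn
from 80–180 ms (< 200 ms by construction). Standardized files place one
unit between 3-s separators of white noise; the noise bed runs under the
calls as well. The separator level is a free parameter (`-28` dBFS RMS by
default; the archival reference level is unknown), which puts good-quality
calls (peak amplitudes 0.55–0.85 full scale) roughly 35–40 dB above the
detector's noise floor in the spectrogram domain.

Quality scenarios transform each unit before placement: **clipped** hard-
limits at 0.5 full scale; **low-amplitude** attenuates by −20 dB (leaving
~15–20 dB of margin: a weak, fragmenting but recoverable contour — at
−30 dB every call sits at the detection threshold and vanishes, a regime in
which reviewer-corrected scoring cannot recover anything); **overlaid**
superimposes a partner call of a different type 40 % into the target (for
series, onto the middle call), with cross-linked annotations. Zips exist
in good quality only. Experimental scenes place units and broadband noise
bursts (0.03–0.25 s band-limited transients, the scratching/digging proxy)
at non-overlapping seeded onsets over a continuous noise bed.

Every operation is deterministic given its spec and seed (seed trees via
`numpy.random.SeedSequence`); re-runs are bit-identical.

## Measurement

Spectrograms use 512-sample hann windows with 50 % overlap (375 Hz ×
1.33 ms resolution at 192 kHz; the window trades off against the 5–30 ms
Zip). Tonality is `1 − spectral flatness` of in-band power. Note a
finite-band estimator bias: a white-noise frame over the 5–50 kHz band
measures ≈ 0.43 ± 0.04, not 0; clean tonal frames measure > 0.9. The
contour of a box takes the per-frame in-band peak frequency (lowest bin on
ties) and drops frames below a tonality floor. Because of the bias the
*cleaning* floor used for feature extraction is 0.55 (the `extract_contour`
default of 0.3 removes nothing from noise); a box whose contour empties at
that floor — a pure-noise detection — falls back to its raw contour, whose
low mean tonality is then exactly what identifies it to the denoiser.

Features per contour: duration, peak-frequency mean/min/max/start/end,
bandwidth, ordinary-least-squares slope, sinuosity (path length over chord
in the time–frequency plane), mean tonality, and a syllable-count estimate
(amplitude bursts along the contour, split at cleaning-induced time gaps).

## Detection

Per profile: the per-frame statistic is the maximum in-band bin power in
dB, smoothed over the profile's window; the noise floor is the per-file
median of that statistic; frames above floor + 8 dB with tonality above
the profile gate are segmented, gaps shorter than one smoothing window are
fused, and segments must fall inside the duration window. Defaults:

| profile | duration gate | smoothing | tonality gate |
|---|---|---|---|
| long | 0.15–3.0 s | 50 ms | 0.30 |
| short | 20–200 ms | 10 ms | 0.35 |
| very_short | 4–30 ms | 3 ms | 0.55 |

The tonality gates step up as the duration gate shrinks: a very short
segment offers few frames of evidence, so it must be strongly tonal, which
keeps single-frame noise excursions out of the very-short detector while
the long/short detectors still pick up broadband transients (left for the
denoiser, as intended). Box frequency bounds are tightened to the segment's
−25 dB energy support; the score is the mean frame tonality.

## Cleanup

The duplicate/fragment filter deletes any box ≥ 90 % temporally contained
in a longer box from a longer-duration profile (trill syllables and call
fragments re-reported by the shorter detectors) and merges same-profile
boxes separated by < 15 ms; both rules iterate to a fixpoint, making the
filter idempotent. These rules are a reconstruction from described
behavior, flagged as such. The denoiser is a seeded random forest over the
acoustic features, trained on detections labelled call/noise by
ground-truth overlap, with a stratified 8:2 learn/test split reported as a
held-out confusion matrix.

## Classification and clustering

The call-type classifier is a seeded random forest (deterministic after
seeding; the family is recorded in the run config). Training calls are
rendered singly over the standard noise bed and — importantly — measured
*through the detector* (intended profile, detected box): training features
then live in exactly the domain the classifier later sees. Measuring
training calls on ground-truth boxes instead leaves a domain shift whose
edge-frame artifacts dominate the class signal. Default training counts
per type: Trill 302, Long whistle 186, Short whistle 1158, Tsak 541,
Zip 70.

Clustering standardizes each feature column, scales groups (frequency 6
columns, duration 1, contour 4) to equal total variance via
`normalize_groups`, applies equal group weights, and runs k-means with
seeded restarts plus a warm start that splits the previous k's best
solution — which guarantees a non-increasing inertia curve. The elbow is
the point of the **log**-inertia curve (axes normalized) farthest from its
chord: relative improvements are scale-free, so a compact rare-type
cluster still registers although its absolute inertia contribution is
negligible. On the pipeline's detected calls this selects 6–7 clusters
whose majority labels cover all five types, typically splitting one of the
abundant types and mixing some Short whistles and Tsaks — consistent with
the transitional forms the generator models.

## Validation protocol

Boxes are matched to ground truth by temporal IoU (default threshold 0.5,
a proxy for human judgement of "correct detection") with greedy one-to-one
assignment in descending overlap order. A box qualifying against exactly
one call is a true positive; a box covering both members of an overlaid
pair is never a true positive in automated scoring, even if it meets the
IoU against one of them (the overlaid pair is "detected together");
remaining boxes are noise (no overlap), fragment (partial overlap with one
call) or cluster (spanning ≥ 2 calls) false positives. A box spanning two
non-overlaid calls of different types is treated as a cluster false
positive. Precision at zero detections is defined as 1.0.

Semi-automated scoring simulates reviewer edits: fragments are extended to
their call's extent, clusters split at call boundaries, overlaid boxes
credited to both calls; duplicates of an already-corrected call are merged
away; noise boxes are uncorrectable. Ground truth is never altered, and
both modes are scored per file with medians and IQRs across files. Because
ground truth here is exact, recall cannot exceed 1; against manual
screening of real recordings it can, since a detector may find calls a
human missed — a semantic difference to keep in mind when comparing
numbers.

## Study configuration and problem sizes

The default `PipelineConfig` renders 50 units per call type for the
good-quality standardized files and 10 for each degraded scenario; eight
denoiser-training scenes (~55 calls + 25 noise events each); ten
experimental sessions of ~70 calls + 20 noise events (0–8 Zips per
session); 2257 classifier-training calls; a rare-class probe of 1500 Short
whistles + 2 Zips (sized so the expected handful of Short-whistle
confusions is a property of the distributions, not of one draw); and
clustering of up to 600 detected calls with `max_clusters = 15` and 25
restarts per k (the library defaults of 50/100 remain available; the
reduced search is ample for ≤ 600 points and keeps a full study run at a
few minutes on one CPU).

## Known limitations

* Synthetic calls are clean FM tones: no harmonics, no reverberation, no
  vocal-tract or room acoustics, no amplitude modulation within syllables.
  Passing validation here demonstrates the pipeline's bookkeeping and the
  detector/classifier contracts — not field performance on real
  recordings.
* The noise model (stationary white bed + band-limited transients) is far
  tamer than cage scratching, vocal overlap of many animals, or equipment
  artifacts.
* The duplicate/fragment filter rules, the per-type acoustic parameters
  and the detector duration gates are package choices, configurable but
  not fitted to any real archive.
* The tonality statistic's noise baseline (~0.43) depends on the band and
  window; other analysis bands require re-checking the cleaning floor and
  the very-short profile's tonality gate.
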