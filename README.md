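# cistrack

Quantitative analysis of organelle maturation in multi-channel 4D
(x, y, z, t) live-cell fluorescence microscopy, built around the budding
yeast Golgi: individual cisternae appear as mobile ~0.5 µm puncta that
change molecular identity over a few minutes, recruiting and releasing
fluorescently tagged markers in sequence (ERGIC → *cis* → medial → *trans*
Golgi → TGN). `cistrack` turns such movies into the statistics this field
reports, and ships a ground-truthed synthetic movie generator so the whole
chain can be validated end to end without any raw data.

## What it computes

- **Puncta detection and tracking** — multi-scale Laplacian-of-Gaussian blob
  detection on anisotropic voxel grids (sub-voxel centers, PSF-corrected
  diameter estimates) and optimal-assignment frame-to-frame linking with gap
  closing.
- **Maturation kinetics** — per-cisterna, per-channel mean-ROI traces
  normalized as *F*/*F*<sub>peak</sub>; the core statistic is the
  **peak-to-peak duration** Δ = t<sub>red peak</sub> − t<sub>green peak</sub>
  of one cisterna, summarized as mean ± SD over n cisternae. Traces are
  averaged after shifting each cisterna so time 0 is the midpoint between
  its two peaks, and marker residency intervals are read off the averaged
  curve at a threshold fraction of its peak.
- **Colocalization** — masked Pearson *r* with automatic Costes
  thresholding: channel B is regressed on A (B ≈ aA + b), the paired
  thresholds (T<sub>A</sub>, aT<sub>A</sub> + b) are lowered until the
  sub-threshold voxels decorrelate (r ≤ 0), and *r* is reported over all
  masked voxels and over the supra-threshold (signal) voxels. Group
  comparisons use Welch's unequal-variance t-test.
- **Line-scan zone segregation** — intensity profiles along a segment
  through a single cisterna and scalar offsets (peak and centroid) between
  the green and red sub-zones.
- **Contact events** — transient (seconds-scale) "hug-and-kiss" contacts
  between mobile cisternae and static ER exit sites, as maximal runs of
  frames within a contact distance.
- **Timeline assembly** — given pairwise mean delays Δ<sub>ij</sub> between
  marker peaks, the global peak times t solve the weighted least squares
  problem min Σ w<sub>ij</sub>(t<sub>j</sub> − t<sub>i</sub> − Δ<sub>ij</sub>)²
  with the anchor marker fixed at 0 (weights n/sd², SD floored at one frame
  interval). A transcription of the published 23-row pairwise delay table is
  bundled (`cistrack.load_reference_delays()`).

## Worked example

`examples/01_delay_recovery.py` simulates ten cisternae whose red-minus-green
peak delays are drawn from N(31, 24.1²) s, imaged every 5 s, and runs the
full pipeline:

```
movie: (70, 2, 21, 51, 67) (t, c, z, y, x), 5.0 s frames
227 spots linked into 16 tracks

estimated deltas (s): [-25.   0.   0.   5.  20.  30.  30.  45.  50.  75.]
true deltas      (s): [-23.8   2.3   3.3   5.9  19.3  29.1  31.3  47.9  50.2  72.5]

peak-to-peak duration: 23.0 +- 29.3 s (n = 10 cisternae); programmed mean was 31.0 s
```

Each estimated delay is a whole number of frame intervals (peaks are located
on the frame grid) and sits within one frame of that cisterna's programmed
truth; the sample mean of 23.0 s reflects this particular draw of ten
deltas, not estimator bias — averaging over 20 replicates recovers the
programmed 31.0 s to within a few seconds (see below). The other examples
cover Costes colocalization on phantoms with known shared-spot fractions,
line-scan zone segregation, ERES contact recovery, and the global marker
timeline (which places the ERGIC markers Grh1, Emp46, Ypt1, Rer1, Erd2 and
Sed5 before the *cis* reference Mnn9, and the TGN-export Rab Ypt32 last).

A thin CLI mirrors the library (`cistrack simulate | detect | track |
contacts | trace | summarize | coloc | profile | timeline | run`); every
movie is a plain TIFF with axis order t,c,z,y,x and physical calibration
(µm, s) embedded in its metadata, and every table a documented CSV.

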