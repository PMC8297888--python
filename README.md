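# topohrv

Topological heart rate variability (HRV) analysis of RR-interval
tachograms, alongside the classical time- and frequency-domain HRV
parameters, with a cross-validated SVM/ROC protocol for comparing
feature sets.

Heart rate variability — the beat-to-beat variation of the interval
between successive heartbeats (RR intervals, ms) — is a standard
non-invasive window on cardiac autonomic regulation, and is altered in
many pathological states such as acute ischemic stroke. `topohrv`
characterises a tachogram through **0-dimensional persistent
homology**: the sequence (r_0, …, r_n) is interpolated piecewise
linearly into a function f, and a threshold t is swept upward through
the sublevel sets f⁻¹((−∞, t]). Connected components are born at local
minima and die when they merge at local maxima (the *elder rule*: the
component with the earlier birth survives); the surviving component is
paired with max f. The resulting multiset of (birth, death) pairs —
the *persistence diagram* D, equivalently the barcode of interval
lengths l_i = d_i − b_i — summarises every accelerating/decelerating
excursion of the heart rhythm at once, from large respiratory swings
down to single-beat jitter.

From the diagram the package derives:

* **length indices** — the number of intervals k, the longest interval
  l_k = max r − min r, mean/median/stdev/sum of the l_i, and the
  2/1 and 3/1 ratios l_{k−1}/l_k, l_{k−2}/l_k;
* **persistent entropy** h = −Σ (l_i/L) log₂(l_i/L) with L = Σ l_i,
  and its normed variant h / log₂ L;
* **threshold indices** — with the length threshold at 5 % of l_k:
  frac5% (fraction of intervals above the threshold), frac100 and
  frac200 (fractions of intervals of at least 100/200 ms), and the
  **signal-to-noise ratio** (total supra-threshold length over total
  sub-threshold length);
* **location indices** — mean/stdev of the midpoints (b_i+d_i)/2,
  births and deaths of the supra-threshold intervals;
* the **topological triangle** T(D) = ABC: a tight triangular
  enclosure of D with base AB on the diagonal {x = y}, fitted by a
  50 × 50 grid search over the two base angles with each side anchored
  so 10 % of the points fall outside it, minimising a least-squares
  objective; its five descriptors are width |AB|, height h, location
  (x of the midpoint of AB), proportion |AC|/|BC|, and misalignment
  (the minimised objective).

The classical comparison set covers mean nni, sdnn, rmssd, pnni50 and
friends in the time domain, and Welch-PSD band powers (VLF/LF/HF),
normalised units and LF/HF ratio in the frequency domain. A
synthetic-data module generates 512-beat recordings with controllable
LF/HF modulation, noise, trend and ectopic beats, so the whole
pipeline is exercisable without any physiological recordings.

## Worked example

```python
from topohrv import con_like, generate_rr, extract_features

series = generate_rr(con_like(seed=5), subject_index=0)   # 512 beats
row, diagram = extract_features(series)
print(f"k = {diagram.n_intervals}")
for name in ("longest_interval", "length_sum", "frac5",
             "pers_entropy", "triangle_height", "sdnn", "hfnu"):
    print(f"{name:>18}: {row[name]:.3f}")
```

prints

```
k = 128
  longest_interval: 131.756
        length_sum: 5974.968
             frac5: 0.930
      pers_entropy: 6.667
   triangle_height: 90.264
              sdnn: 23.915
              hfnu: 64.954
```

The recording's 512 beats produce 128 persistence intervals (one per
strict local minimum of the tachogram); the longest spans the full
131.8 ms range of the series; 93 % of the intervals exceed 5 % of that
range; the entropy of 6.67 bits (close to log₂ 128 = 7) says the
interval lengths are spread rather than dominated by a few excursions;
the triangle height of 90 ms measures how far the diagram's apex
reaches above the diagonal. The classical sdnn of 23.9 ms and a
HF-dominated spectrum (hfnu ≈ 65) are typical of a healthy-like
resting recording with pronounced respiratory sinus arrhythmia.

The same pipeline is available from the shell:

```bash
topohrv simulate --preset con -n 10 --seed 5 -o rr/
topohrv compute rr/*.csv -o features.csv
topohrv evaluate features.csv --search-all --seed 0 -o models.csv
topohrv diagram rr/con-000.csv -o diagram.csv --plot diagram.png
```

`evaluate --search-all` reproduces the model-search protocol: all 420
quadruples drawn from the 7 base topological descriptors plus at most
2 of the 5 triangle descriptors, each scored by a linear-kernel SVM
under stratified 3-fold cross-validation with per-fold
standardisation, reported as the AUC of the vertically averaged ROC
curve and the mean ± sd of the fold AUCs.

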