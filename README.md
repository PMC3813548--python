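# seegconn

Functional-connectivity analysis of interictal stereo-EEG (SEEG) for
predicting the outcome of epilepsy surgery.

In medically intractable temporal lobe epilepsy, resective surgery fails to
stop seizures in roughly half of patients, and better presurgical biomarkers
are needed. `seegconn` implements a deliberately simple one: during
seizure-free (interictal) periods, estimate the pairwise Pearson correlation
between SEEG channels sampled across the temporal lobe, and summarise each
patient by just two numbers — the mean and the standard deviation of the
off-diagonal connectivity. Patients whose temporal-lobe networks are weakly
and homogeneously connected tend to become seizure-free after temporal
lobectomy; patients with strong, heterogeneous connectivity tend to relapse.
A straight line in this two-dimensional feature plane separates the groups.

## The method

For `n` simultaneously recorded traces `V_i(t)`, `t = 1…T`, the functional
connectivity matrix is

    C_ij = cov(V_i, V_j) / (σ_i σ_j)          (Pearson's r)

with `C_ii = 1` and all entries in `[−1, 1]`. The pipeline:

1. **Preprocessing** — zero-phase frequency-domain band-pass filter
   (pass band 5–50 Hz; stops at DC and 60 Hz, raised-cosine upper
   transition), per-channel z-scoring, hard clipping of residual spikes at
   ±5 SD.
2. **Segment selection** — three non-overlapping interictal segments of
   ~90 s (±20 %, stretched around spike-dense stretches), all ending at
   least 30 minutes before the first seizure.
3. **Connectivity** — one Pearson matrix per segment; elementwise average
   across segments; contact-level matrices reduced to a 9-region
   temporal-lobe parcellation (HH, HT, A, STG, MTG, ITG, FG, PHG, TP).
4. **Features** — mean and sample SD of the off-diagonal entries: the
   patient's `(x, y)` coordinates.
5. **Classification** — soft-margin linear support-vector classifier (or,
   alternatively, a pooled-covariance linear discriminant); performance
   (sensitivity, specificity, accuracy) estimated by leave-one-out;
   significance by a label-permutation test (default 10,000 shuffles,
   p = fraction of permutations with a metric ≥ the observed one); group
   differences per coordinate by the two-sided Wilcoxon rank-sum test.

Because no patient SEEG with outcome labels is publicly available, the
package includes a first-class synthetic-cohort generator: band-limited
correlated Gaussian recordings whose population correlation matrix has a
prescribed off-diagonal mean and SD (truncated-normal draws projected to the
nearest correlation matrix), with realistic artifacts (60 Hz mains, slow
drift, biexponential spike transients) that the preprocessing must remove.

## Worked example

`examples/` contains one narrative script per capability. The end-to-end
run (`python examples/04_full_pipeline.py`, a reduced 6 + 5 patient cohort)
prints:

```
patient features (x = mean connectivity, y = SD):
  P01  seizure-free  x=+0.175 y=0.047
  P02  seizure-free  x=+0.230 y=0.111
  ...
  N05  recurrence    x=+0.390 y=0.104

leave-one-out: accuracy=1.000 sensitivity=1.000 specificity=1.000
permutation p-values (500 draws): accuracy 0.0000, sensitivity 0.0020, specificity 0.0140
rank-sum mean_connectivity: W=21, p=4.33e-03
rank-sum sd_connectivity: W=22, p=8.66e-03
```

Each patient is one point; seizure-free patients sit at low mean/SD and the
leave-one-out classifier separates the groups perfectly here, with no random
relabelling of outcomes reaching the observed accuracy (p below 1/500). The
same analysis is scriptable from the shell:

```bash
seegconn simulate --out cohort/ --n-pos 4 --n-neg 4 --exclusion-min 1 --seed 7
seegconn run-all --out results/ --perms 1000 --seed 7
seegconn classify results/features.csv --out report.json --classifier svc
```

`run_pipeline` writes per-patient segment matrices, averaged region-level
matrices, the features table, group region-pair averages (with absent pairs
marked), and a JSON report carrying the config hash and seeds needed to
reproduce it byte-for-byte.

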