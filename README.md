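# pelvitherm

Proton-resonance-frequency-shift (PRFS) MR-thermometry reconstruction,
probe benchmarking, and imaging-based session selection for MR-guided deep
pelvic hyperthermia.

During hyperthermia treatment of pelvic tumors, tissue is heated to
40–44 °C while a gradient-echo MR sequence maps temperature change
non-invasively. The water-proton resonance frequency varies linearly with
temperature, so the phase difference between a treatment scan φₙ and the
pre-treatment reference φ₀₀ encodes the temperature change

    ΔT(n) = wrap(φₙ − φ₀₀) / (γ · α · B₀ · TE)

with γ = 267.5 × 10⁶ rad/T·s, α the PRF change coefficient (ppm/°C),
B₀ = 1.5 T and TE = 19.1 ms. In the pelvis this signal is badly confounded:
the static field drifts (corrected here by a per-slice 2-D polynomial fit
anchored on body fat, which shows no PRFS shift), low-SNR voxels spike
(masked by a 3×3-neighborhood deviation rule), and moving gastrointestinal
air creates susceptibility artifacts that masquerade as temperature.
Remaining outliers are removed by an |ΔT| threshold optimized against
intraluminal probe readings — the gold standard acquired in the bladder,
rectum and vagina every 5 min at 1 cm steps.

The package answers two questions about this pipeline:

1. **How good is MR thermometry against the probes?** Per session and
   location: accuracy (mean |T̄_MR − T̄_probe|), temporal precision (sample
   SD of the ROI mean across scans) and bias (signed mean difference).
2. **Can a session be selected *before* treatment?** Four imaging features
   from the two baseline scans — the Jaccard overlap J(A,B) = |A∩B|/|A∪B|
   of the air masks (air motion), air volume, fat volume, and the minimum
   air-to-ROI distance — are scored by ROC/AUC against the "session
   accuracy ≤ 1 °C" label, with the operating cut-off at the curve point
   nearest (0, 1).

Because clinical data of this kind is not public, the package ships a
first-class synthetic-session generator (`pelvitherm.simulate`) producing
anatomy, ground-truth heating, encoded phase/magnitude scans with drift,
noise and air-motion-scaled susceptibility artifacts, and probe traces —
so every stage is tested end to end against a known truth.

## Worked example

```python
from pelvitherm import ScanGeometry, simulate_session
from pelvitherm.pipeline import process_session

session = simulate_session(
    geometry=ScanGeometry(matrix=128, n_slices=15),
    air_motion_fraction=0.2,   # Jaccard ~ 0.8 between the baseline air masks
    air_volume_ml=200.0,
    seed=42,
)
features, roi_series, metrics, threshold = process_session(session)
print(f"Jaccard coefficient : {features.jaccard:.3f}")
for loc, m in metrics.per_location.items():
    print(f"{loc:8s} accuracy {m.accuracy_c:.2f} °C  precision {m.precision_c:.2f} °C  "
          f"bias {m.bias_c:+.2f} °C")
print(f"session accuracy    : {metrics.session_accuracy_c:.2f} °C  "
      f"acceptable: {metrics.acceptable}")
```

prints

```
Jaccard coefficient : 0.800
bladder  accuracy 2.76 °C  precision 1.63 °C  bias +2.72 °C
rectum   accuracy 1.30 °C  precision 1.06 °C  bias +1.27 °C
vagina   accuracy 0.28 °C  precision 1.50 °C  bias +0.15 °C
session accuracy    : 1.45 °C  acceptable: False
```

The injected air motion (1 − J = 0.2) corrupts the ROIs nearest the moving
air: the location-averaged accuracy exceeds the 1 °C acceptability bound,
so this session would be flagged by the prospective Jaccard criterion. The
same chain is available from the shell:

```bash
pelvitherm simulate --seed 42 --motion 0.2 --out session/
pelvitherm reconstruct --session session/ --optimize-threshold --out recon/
pelvitherm features --session session/ --out features.csv
pelvitherm run --config cohort.yaml --out cohort/   # full all-vs-selected study
```

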