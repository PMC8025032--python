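# pactangio

Quantitative analysis of photoacoustic computed tomography (PACT) breast
angiograms for assessing tumor response to neoadjuvant chemotherapy (NAC).

Ring-array PACT resolves the microvasculature of the whole breast without
contrast agents. Breast cancer shows up in these angiograms as a region of
dense, disordered vessels (tumor-associated angiogenesis), and vascular
regression under systemic therapy is measurable long before morphology
changes. `pactangio` implements the full quantitative chain for such
images, plus the synthetic data needed to test every stage:

* **Vessel density** — skeletonize the maximum-amplitude-projection (MAP)
  angiogram, break centerlines into independent vessels at junctions,
  drop segments under 3 px, and count distinct vessels per sliding
  2 mm × 2 mm window, divided by the window area.
* **Windowed entropy** — per 1 mm window `W` of the background-thresholded
  MAP, `H = −Σᵢ Pᵢ log₂ Pᵢ` over an intensity histogram (32 global bins).
* **Rotational-SVD anisotropy** — rotate each window through θ = 0°…170°
  in 10° steps; the normalized SVD dominancy `N_SVD(θ) = σ₁/Σₖσₖ` varies
  strongly with θ for a straight vessel and weakly for disordered texture.
  Directionality `D = maxθ N_SVD − minθ N_SVD`; anisotropy `A = 1/(D+ε)`,
  ε = 0.01.
* **Anisotropy-weighted entropy** — `E = H·exp(−k/A)` with k = 30, which
  suppresses the smooth, directional vasculature of healthy tissue.
  Thresholding the `E` map at the whole-breast mean + 1.4 SD and keeping
  the largest connected component segments the tumor; `(E + β)·M_PA`
  (β = 0.07) yields a lesion-enhanced angiogram.
* **Statistics** — ROI-vs-healthy one-tailed Welch t-tests on
  non-overlapping window samples of density, entropy, and anisotropy,
  reported per treatment time point.
* **Simulator** — a 2D full-ring forward model (220 mm ring, 512
  elements, 2.25 MHz center frequency; analytic uniform-sphere N-waves,
  optional band-pass response) with universal back-projection
  (`b(t) = 2p − 2t·dp/dt`) reconstruction and `e^{0.6·depth(cm)}` depth
  compensation, plus a breast-mimicking inclusion phantom (seven absorbers
  of 1–3.5 mm diameter at 2.1× background absorption) and a two-compartment
  synthetic vascular scene generator with a tunable response fraction.

## Worked example

```python
import pactangio as pa

# Phantom experiment: simulate, reconstruct, detect
run = pa.phantom_experiment()
print(len(run["detections"]))                      # 7
print(min(d for _, d in run["matched"]))           # 1.0   (mm)
print(round(run["contrast"], 3))                   # 2.104 (vs 2.1 ground truth)

# Synthetic treatment series: baseline, mid-treatment, complete response
spec = pa.VascularSceneSpec(seed=11)
report = pa.scene_series_report(spec, response_fractions=(0.0, 0.5, 1.0))
print(report[report.region == "roi"].head())
```

The phantom run detects all seven inclusions including the 1 mm one, and
the inclusion/background amplitude ratio of the reconstruction (2.104)
recovers the built-in 2.1× absorption contrast. The treatment series
prints, per time point, ROI mean ± SE and the one-tailed Welch p-value
against healthy tissue; for seed 11 the ROI vessel density falls from
1.30 mm⁻² (p = 2.5×10⁻⁴) at baseline to 0.78 mm⁻² (p = 0.55) at complete
response, entropy from 3.87 bits (p = 5.6×10⁻²³) to 2.51 bits (p = 0.73),
and the segmented tumor long axis from 0.81 cm to 0.43 cm — the signature
of a responding cancer.

A command-line interface mirrors the library
(`pactangio phantom|scene|simulate|reconstruct|preprocess|density|irregularity|segment|report|pipeline`).

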