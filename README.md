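# qcest

Quantitative CEST (qCEST) analysis of intervertebral disc MRI: estimation of
the pH-sensitive glycosaminoglycan (GAG) hydroxyl proton exchange rate
`k_sw` from multi-power CEST Z-spectra, together with the surrounding
pipeline — WASSR B0 correction, T1/T2/T1ρ relaxometry mapping, pH
calibration, biomarker correlation, and ROC classification of degenerated
vs healthy discs.

## Who this is for

Disc degeneration lowers intradiscal pH (healthy ≈ 7.2, degenerated ≈ 6.3),
and acid-catalysed proton exchange between GAG hydroxyls (+1.0 ppm) and
water speeds up as pH falls. qCEST turns that into an imaging biomarker:
unlike plain CEST contrast, the estimated exchange rate is independent of
T1, T2 and solute concentration. This package is for imaging scientists who
want a tested, reproducible implementation of that analysis — and, because
in vivo data of this kind is rarely shareable, it ships a two-pool
Bloch–McConnell phantom generator so every stage can be validated by
parameter recovery against known ground truth.

## The method

For each saturation amplitude B1 (four levels: 0.73, 1.22, 1.71, 2.45 µT,
from flip angles via `B1 = flip/(γ·t_p)`), the inverse CEST difference is
formed from the B0-corrected Z-spectrum:

    CESTR_ind = 1/Z(+1.0 ppm) − 1/Z(−1.0 ppm)

Under the pulsed-saturation two-pool model, `1/CESTR_ind` is linear in
`1/ω1²` (the ω-plot):

    1/CESTR_ind ≈ R1w/(DC·f_r·k_sw·c1) · [ 1 + k_sw(R2s + k_sw)·c2² / ω1² ]

with duty cycle `DC`, Gaussian-pulse shape constants
`c1 = σ√(2π)/t_p`, `c2 = c1·2^(1/4)`, and `ω1 = 2π·γ·B1`. Ordinary least
squares gives slope `m` and intercept `n`, and the exchange rate follows
from the slope/intercept ratio — solute fraction `f_r` and `R1w` cancel:

    k_sw = [ √(R2s² + 4m/(n·c2²)) − R2s ] / 2

The pH calibration `k_sw = a·10^(−pH+8) + b` is fitted by least squares and
inverted as `pH = 8 − log10((k_sw − b)/a)`; disc-level statistics (Pearson
correlation with RT-PCR relative quantification, ROC with Youden operating
point) close the loop.

## Worked example

```python
import numpy as np
from qcest import (TwoPoolModel, disc_cest_scheme, wassr_scheme, QcestConfig,
                   simulate_pulsed_cest_zspectrum, simulate_wassr_spectrum,
                   estimate_b0_shift_mscf, correct_zspectrum, estimate_ksw,
                   CalibrationModel, ph_from_ksw)

pool = TwoPoolModel(k_sw=1000.0)          # ground truth: k_sw = 1000 1/s
scheme = disc_cest_scheme()               # 39 pulses, 4 B1 levels, 10 offsets
zset = simulate_pulsed_cest_zspectrum(pool, scheme, b0_shift_ppm=0.1)

wassr = simulate_wassr_spectrum(pool, wassr_scheme(), b0_shift_ppm=0.1)
shift = estimate_b0_shift_mscf(wassr)
print(f"estimated B0 shift: {shift.shift_ppm:+.4f} ppm (true +0.1000)")

corrected = correct_zspectrum(zset, shift.shift_ppm)
ksw, fit = estimate_ksw(corrected, QcestConfig())
print(f"omega-plot fit: R^2 = {fit.r_squared:.4f}")
print(f"estimated k_sw = {ksw:.0f} 1/s")

cal = CalibrationModel(a=1.3, b=248.2)
print(f"k_sw at pH 7.2 per calibration: {float(cal.ksw(7.2)):.1f} 1/s")
print(f"pH read back from k_sw = 300:   {ph_from_ksw(cal, 300.0):.2f}")
```

prints

```
estimated B0 shift: +0.1016 ppm (true +0.1000)
omega-plot fit: R^2 = 0.9952
estimated k_sw = 370 1/s
k_sw at pH 7.2 per calibration: 256.4 1/s
pH read back from k_sw = 300:   6.40
```

The WASSR step recovers the simulated field offset to ~2 mppm and the
ω-plot is highly linear (R² > 0.99). The estimated exchange rate of
370 1/s against a true 1000 1/s shows the known systematic compression of
the ω-plot linearization at 3 T, where the +1.0 ppm solute shift is
comparable to the saturation amplitude; the estimate is monotone in the
true rate and concentration-independent, and the pH calibration — fitted
in estimated-rate space — absorbs the bias. See `docs/methods.md` for the
quantitative picture.

A full phantom-to-report run is available from the shell:

```
qcest run-all --seed 42 --out results/
```

which writes per-disc tables (`discs.csv`), the fitted calibration, ROC
curve, biomarker correlations, a QC report and the resolved config.

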