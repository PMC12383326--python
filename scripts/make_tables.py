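"""Regenerate the bundled observer/illuminant CSV tables.

The package ships synthetic stand-ins for the measured CIE reference data:

* ``cmf_cie1931_2deg_synthetic.csv`` — the multi-lobe piecewise-Gaussian
  analytic fit to the CIE 1931 2-degree color-matching functions of
  Wyman, Sloan & Shirley, "Simple Analytic Approximations to the CIE XYZ
  Color Matching Functions" (JCGT 2013), tabulated 380-780 nm at 1 nm.
  The small negative excursion of the x-bar fit is clipped to zero so the
  table satisfies the nonnegativity invariant of the observer weights.
* ``illuminant_d65_synthetic.csv`` — Planck blackbody spectral radiance at
  6504 K, normalized to 100 at 560 nm: a smooth daylight-shaped curve used
  as the working "D65-like" illuminant.

Run from the repository root:  python scripts/make_tables.py
"""

from pathlib import Path

import numpy as np

OUT = Path(__file__).resolve().parents[1] / "src" / "specsave" / "data"


def piecewise_gauss(x, mu, s1, s2):
    s = np.where(x < mu, s1, s2)
    return np.exp(-0.5 * ((x - mu) / s) ** 2)


def cmf_1931_analytic(w):
    xbar = (
        1.056 * piecewise_gauss(w, 599.8, 37.9, 31.0)
        + 0.362 * piecewise_gauss(w, 442.0, 16.0, 26.7)
        - 0.065 * piecewise_gauss(w, 501.1, 20.4, 26.2)
    )
    ybar = 0.821 * piecewise_gauss(w, 568.8, 46.9, 40.5) + 0.286 * piecewise_gauss(
        w, 530.9, 16.3, 31.1
    )
    zbar = 1.217 * piecewise_gauss(w, 437.0, 11.8, 36.0) + 0.681 * piecewise_gauss(
        w, 459.0, 26.0, 13.8
    )
    return np.clip(xbar, 0, None), np.clip(ybar, 0, None), np.clip(zbar, 0, None)


def planck_relative(w_nm, temperature_k=6504.0):
    c2 = 1.4388e-2  # second radiation constant, m*K
    lam = w_nm * 1e-9
    power = lam**-5 / np.expm1(c2 / (lam * temperature_k))
    ref = (560e-9) ** -5 / np.expm1(c2 / (560e-9 * temperature_k))
    return 100.0 * power / ref


def main():
    w = np.arange(380, 781, dtype=float)
    xbar, ybar, zbar = cmf_1931_analytic(w)
    lines = ["wavelength_nm,xbar,ybar,zbar"]
    for row in zip(w, xbar, ybar, zbar):
        lines.append("%.0f,%.6f,%.6f,%.6f" % row)
    (OUT / "cmf_cie1931_2deg_synthetic.csv").write_text("\n".join(lines) + "\n")

    d65 = planck_relative(w)
    lines = ["wavelength_nm,power"]
    for wl, p in zip(w, d65):
        lines.append("%.0f,%.6f" % (wl, p))
    (OUT / "illuminant_d65_synthetic.csv").write_text("\n".join(lines) + "\n")
    print("wrote tables to", OUT)


if __name__ == "__main__":
    main()
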