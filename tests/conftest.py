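import numpy as np
import pytest

from photoscreen.uv_metrics import AbsorbanceSpectrum


@pytest.fixture
def flat_spectrum() -> AbsorbanceSpectrum:
    """A = 1 everywhere on 290..400 at 1 nm."""
    wl = np.arange(290.0, 401.0)
    return AbsorbanceSpectrum(wl, np.ones_like(wl), sample_id="flat")


@pytest.fixture
def gaussian_spectrum() -> AbsorbanceSpectrum:
    """Single Gaussian band: center 305 nm, sigma 10 nm, peak 1."""
    wl = np.arange(290.0, 401.0)
    a = np.exp(-((wl - 305.0) ** 2) / (2 * 10.0 ** 2))
    return AbsorbanceSpectrum(wl, a, sample_id="gauss305")


#: The published feature table used as a fixture: (id, rt, formula, adduct,
#: observed m/z, printed calculated m/z, isomer coincidence, level).
TABLE1_ROWS = [
    (1, 2.81, "C28H38N4O6", "[M+H]+", 527.2838, 527.2864, 4, 4),
    (2, 6.37, "C26H29NO5", "[M+2ACN+H]+", 518.2643, 518.2650, 7, 4),
    (3, 14.50, "C22H26O6", "[M+H]+", 387.1814, 387.1802, 13, 4),
    (4, 15.22, "C17H30N2O3", "[M+2ACN+H]+", 393.2877, 393.2860, 1, 3),
    (5, 15.69, "C26H28O6", "[M+H]+", 437.1947, 437.1959, 5, 4),
    (6, 16.30, "C24H30O6", "[M+H]+", 415.2129, 415.2115, 9, 4),
    (7, 20.00, "C37H55NO6", "[M+2ACN+H]+", 692.4602, 692.4633, 1, 3),
    (8, 20.12, "C32H54N4O7", "[M+ACN+H]+", 648.4338, 648.4331, 6, 4),
    (9, 21.07, "C35H63NO3", "[M+H]+", 546.4901, 546.4881, 3, 4),
    (10, 21.79, "C42H75N7O17", "[M+ACN+H]+", 991.5576, 991.5557, 1, 3),
    (11, 22.70, "C21H31NO2", "[M+2ACN+H]+", 412.2968, 412.2959, 1, 3),
    (12, 22.85, "C27H37N7O7", "[M+2ACN+H]+", 654.3348, 654.3358, 1, 3),
    (13, 22.93, "C31H42N2O7S", "[M+2ACN+H]+", 669.3346, 669.3317, 1, 3),
    (14, 23.02, "C42H63O4P", "[M+H]+", 663.4566, 663.4537, 1, 3),
    (15, 23.34, "C34H60N4O10", "[M+H]+", 685.4385, 685.4382, 1, 3),
    (16, 23.44, "C22H38O2", "[M+ACN+H]+", 376.3202, 376.3210, 3, 4),
    (17, 25.29, "C32H26O10", "[M+ACN+H]+", 612.1849, 612.1864, 8, 4),
]

#: Rows whose printed calculated m/z differs from standard monoisotopic
#: arithmetic in the 4th decimal (source software's mass table unknown).
TABLE1_LOOSE_ROWS = {2, 10, 13}


@pytest.fixture
def table1_rows():
    return TABLE1_ROWS


def dense_lambda_c_oracle(spectrum: AbsorbanceSpectrum,
                          step: float = 0.01) -> float:
    """Brute-force critical wavelength: cumulative sums on a dense grid.

    Independent of the package implementation: linear interpolation onto
    a `step` grid, left-Riemann-free cumulative trapezoid via cumsum of
    segment means, then first grid point reaching 90% of the total.
    """
    grid = np.arange(290.0, 400.0 + step / 2, step)
    a = np.clip(np.interp(grid, spectrum.wavelengths, spectrum.absorbance),
                0.0, None)
    seg = 0.5 * (a[1:] + a[:-1]) * step
    cum = np.cumsum(seg)
    total = cum[-1]
    idx = int(np.searchsorted(cum, 0.9 * total))
    return float(grid[min(idx + 1, len(grid) - 1)])
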