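"""Amino-acid substitution models for quartet likelihood computations.

Provides the LG general-matrix model with discrete-gamma rate variation
(equal-probability categories, category rate equal to the category mean),
plus a Poisson (equal-rates, equal-frequencies) model for simulations and
quick sanity checks. The rate matrix is built as ``R @ diag(pi)`` from the
symmetric exchangeability matrix ``R`` and stationary frequencies ``pi``,
then scaled so the expected substitution rate at stationarity is one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

#: Canonical amino-acid ordering (PAML convention); index i encodes AMINO_ACIDS[i].
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Code used for a missing/ambiguous residue after normalization.
MISSING = -1

# Published LG exchangeabilities, lower triangle in column-major order
# ((1,0),(2,0),...,(19,0),(2,1),...), and stationary frequencies, both in
# AMINO_ACIDS order.
_LG_EXCH_LOWER = [
    0.425093, 0.276818, 0.395144, 2.489084, 0.969894, 1.038545,
    2.06604, 0.358858, 0.14983, 0.395337, 0.536518, 1.124035,
    0.253701, 1.177651, 4.727182, 2.139501, 0.180717, 0.218959,
    2.54787, 0.751878, 0.123954, 0.534551, 2.807908, 0.36397,
    0.390192, 2.426601, 0.126991, 0.301848, 6.326067, 0.484133,
    0.052722, 0.332533, 0.858151, 0.578987, 0.593607, 0.31444,
    0.170887, 5.076149, 0.528768, 1.695752, 0.541712, 1.437645,
    4.509238, 0.191503, 0.068427, 2.145078, 0.371004, 0.089525,
    0.161787, 4.008358, 2.000679, 0.045376, 0.612025, 0.083688,
    0.062556, 0.523386, 5.24387, 0.844926, 0.927114, 0.01069,
    0.015076, 0.282959, 0.025548, 0.017416, 0.394456, 1.240275,
    0.42586, 0.02989, 0.135107, 0.037967, 0.084808, 0.003499,
    0.569265, 0.640543, 0.320627, 0.594007, 0.013266, 0.89368,
    1.105251, 0.075382, 2.784478, 1.14348, 0.670128, 1.165532,
    1.959291, 4.128591, 0.267959, 4.813505, 0.072854, 0.582457,
    3.234294, 1.672569, 0.035855, 0.624294, 1.223828, 1.080136,
    0.236199, 0.257336, 0.210332, 0.348847, 0.423881, 0.044265,
    0.069673, 1.807177, 0.173735, 0.018811, 0.419409, 0.611973,
    0.604545, 0.077852, 0.120037, 0.245034, 0.311484, 0.008705,
    0.044261, 0.296636, 0.139538, 0.089586, 0.196961, 1.73999,
    0.129836, 0.268491, 0.054679, 0.076701, 0.108882, 0.366317,
    0.697264, 0.442472, 0.682139, 0.508851, 0.990012, 0.584262,
    0.597054, 5.306834, 0.119013, 4.145067, 0.159069, 4.273607,
    1.112727, 0.078281, 0.064105, 1.033739, 0.11166, 0.232523,
    10.649107, 0.1375, 6.312358, 2.592692, 0.24906, 0.182287,
    0.302936, 0.619632, 0.299648, 1.702745, 0.656604, 0.023918,
    0.390322, 0.748683, 1.136863, 0.049906, 0.131932, 0.185202,
    1.798853, 0.099849, 0.34696, 2.020366, 0.696175, 0.481306,
    1.898718, 0.094464, 0.361819, 0.165001, 2.457121, 7.803902,
    0.654683, 1.338132, 0.571468, 0.095131, 0.089613, 0.296501,
    6.472279, 0.248862, 0.400547, 0.098369, 0.140825, 0.245841,
    2.188158, 3.151815, 0.18951, 0.249313,
]

_LG_FREQS = [
    0.07906592093407908, 0.05594094405905594, 0.04197695802304198, 0.053051946948053055, 0.012936987063012939,
    0.040766959233040766, 0.07158592841407159, 0.05733694266305734, 0.022354977645022357, 0.06215693784306216,
    0.09908090091909909, 0.0645999354000646, 0.022950977049022953, 0.042301957698042306, 0.04403995596004404,
    0.0611969388030612, 0.05328694671305329, 0.012065987934012068, 0.034154965845034156, 0.06914693085306915,
]


def _expand_lower_triangle(values) -> np.ndarray:
    mat = np.zeros((20, 20))
    k = 0
    for j in range(20):
        for i in range(j + 1, 20):
            mat[i, j] = mat[j, i] = values[k]
            k += 1
    assert k == len(values)
    return mat


def discrete_gamma_rates(shape: float, n_categories: int = 10) -> np.ndarray:
    """Mean rates of ``n_categories`` equal-probability discrete-gamma classes.

    Uses the standard mean-of-category discretization: category boundaries are
    gamma quantiles and each category rate is the conditional mean within its
    boundaries, renormalized to overall mean one.
    """
    if shape <= 0:
        raise ValueError(f"gamma shape must be positive, got {shape}")
    n = n_categories
    # mean-one gamma: shape a, scale 1/a
    bounds = _gamma_dist.ppf(np.linspace(0.0, 1.0, n + 1), a=shape, scale=1.0 / shape)
    # conditional means via the regularized incomplete gamma of shape a+1
    upper = gammainc(shape + 1.0, shape * bounds[1:])
    lower = gammainc(shape + 1.0, shape * bounds[:-1])
    rates = n * (upper - lower)
    rates = np.where(np.isfinite(rates) & (rates > 0), rates, 1e-12)
    return rates / rates.mean()


@dataclass
class SubstitutionModel:
    """Reversible amino-acid model with discrete-gamma rate heterogeneity.

    Parameters
    ----------
    exchangeabilities:
        Symmetric non-negative 20x20 matrix of relative exchange rates.
    frequencies:
        Stationary amino-acid frequencies (sum to one), AMINO_ACIDS order.
    gamma_shape:
        Shape of the gamma distribution of site rates; ``None`` disables
        rate heterogeneity (single category of rate one).
    n_categories:
        Number of equal-probability discrete rate categories.
    """

    exchangeabilities: np.ndarray
    frequencies: np.ndarray
    gamma_shape: float | None = 1.0
    n_categories: int = 10
    name: str = "custom"

    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.exchangeabilities = np.asarray(self.exchangeabilities, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.exchangeabilities.shape != (20, 20):
            raise ValueError("exchangeabilities must be 20x20")
        if not np.allclose(self.exchangeabilities, self.exchangeabilities.T):
            raise ValueError("exchangeabilities must be symmetric")
        if np.any(self.exchangeabilities < 0):
            raise ValueError("exchangeabilities must be non-negative")
        if self.frequencies.shape != (20,) or not np.isclose(self.frequencies.sum(), 1.0):
            raise ValueError("frequencies must be a 20-vector summing to 1")

    @property
    def category_rates(self) -> np.ndarray:
        if self.gamma_shape is None:
            return np.ones(1)
        return discrete_gamma_rates(self.gamma_shape, self.n_categories)

    def rate_matrix(self) -> np.ndarray:
        """Normalized instantaneous rate matrix Q = R diag(pi), mean rate 1."""
        q = self.exchangeabilities * self.frequencies[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        scale = -(self.frequencies * np.diag(q)).sum()
        return q / scale

    def _eigendecomposition(self):
        # Reversibility: diag(sqrt(pi)) Q diag(1/sqrt(pi)) is symmetric, so Q has
        # a real spectrum and P(t) = D^-1 U exp(L t) U' D with orthogonal U.
        if self._eig is None:
            pi = self.frequencies
            sqrt_pi = np.sqrt(pi)
            q = self.rate_matrix()
            sym = sqrt_pi[:, None] * q / sqrt_pi[None, :]
            eigval, eigvec = np.linalg.eigh((sym + sym.T) / 2.0)
            right = eigvec / sqrt_pi[:, None]
            left = eigvec.T * sqrt_pi[None, :]
            object.__setattr__(self, "_eig", (eigval, right, left))
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Q t); rows are the source state."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        eigval, right, left = self._eigendecomposition()
        p = (right * np.exp(eigval * t)[None, :]) @ left
        if not np.all(np.isfinite(p)):
            raise FloatingPointError(f"non-finite transition matrix at t={t}")
        return np.clip(p, 0.0, None)

    def transition_matrices(self, ts) -> np.ndarray:
        """Stacked P(t) for several branch lengths at once, shape (len(ts), 20, 20)."""
        ts = np.asarray(ts, dtype=float)
        if np.any(ts < 0):
            raise ValueError("branch lengths must be non-negative")
        eigval, right, left = self._eigendecomposition()
        expo = np.exp(ts[:, None] * eigval[None, :])
        p = np.einsum("ik,ck,kj->cij", right, expo, left)
        if not np.all(np.isfinite(p)):
            raise FloatingPointError("non-finite transition matrix")
        return np.clip(p, 0.0, None)

    def with_shape(self, shape: float | None) -> "SubstitutionModel":
        return SubstitutionModel(
            self.exchangeabilities, self.frequencies, shape, self.n_categories, self.name
        )


def lg_model(gamma_shape: float | None = 1.0, n_categories: int = 10) -> SubstitutionModel:
    """The LG amino-acid model (published empirical matrix), LG+Gamma by default."""
    return SubstitutionModel(
        _expand_lower_triangle(_LG_EXCH_LOWER),
        np.array(_LG_FREQS) / np.sum(_LG_FREQS),
        gamma_shape,
        n_categories,
        name="LG",
    )


def poisson_model(gamma_shape: float | None = None) -> SubstitutionModel:
    """Equal-rates, equal-frequencies model (amino-acid Jukes-Cantor analogue)."""
    exch = np.ones((20, 20))
    np.fill_diagonal(exch, 0.0)
    return SubstitutionModel(exch, np.full(20, 0.05), gamma_shape, 10, name="Poisson")


def encode_residue(ch: str) -> int:
    """Map a residue character to 0-19, or MISSING for gap/ambiguity."""
    idx = AMINO_ACIDS.find(ch)
    return idx if idx >= 0 else MISSING
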