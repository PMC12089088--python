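"""Linear structure-property models for the coronene fractal families.

Spectral properties (total pi-energy, HOMO-LUMO gap, per-atom energies,
resonance energy, spectral diameter) are regressed against a single
descriptor by ordinary least squares, ``P = R * x + c``.  The descriptor is
the k=2 modified reverse first Zagreb index (``M2RM1``) for the total
pi-energy and the corresponding graph entropy (``I_M2RM1``) for the other
properties — the combination found to correlate best across the families.

The reference fitting set is the eleven structures for which spectral
properties are tabulated: ZHCF(1-4), AHCF(1-3) and RCF(1-4) with the square
convention m = n.  Property values can be taken from that published table
(``mode="paper"``) or recomputed from scratch (``mode="computed"``).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .entropy import entropy_closed_form
from .generator import FractalSpec, generate
from .indices import index_value_closed_form
from . import spectral as spec_mod

#: The eleven reference structures, in table order.
REFERENCE_STRUCTURES: tuple[tuple[str, FractalSpec], ...] = tuple(
    (s.label if s.family != "RCF" else f"RCF({s.n})", s)
    for s in (
        [FractalSpec("ZHCF", n) for n in (1, 2, 3, 4)]
        + [FractalSpec("AHCF", n) for n in (1, 2, 3)]
        + [FractalSpec("RCF", n, n) for n in (1, 2, 3, 4)]
    )
)

PROPERTY_NAMES = ("e_pi", "gap", "e_pi_per_atom", "deloc_per_atom",
                  "re_per_atom", "sd")

#: Published spectral properties (beta units) of the reference structures.
#: Columns: e_pi, gap, e_pi_per_atom, deloc_per_atom, re_per_atom, sd.
TABLE_SPECTRA: dict[str, dict[str, float]] = {
    "ZHCF(1)": {"e_pi": 194.662, "gap": 0.7638, "e_pi_per_atom": 1.475,
                "deloc_per_atom": 0.474712, "re_per_atom": 0.156614, "sd": 5.5937},
    "ZHCF(2)": {"e_pi": 765.926, "gap": 0.65732, "e_pi_per_atom": 1.484,
                "deloc_per_atom": 0.484353, "re_per_atom": 0.159251, "sd": 5.64926},
    "ZHCF(3)": {"e_pi": 1713.792, "gap": 0.62768, "e_pi_per_atom": 1.488,
                "deloc_per_atom": 0.487666, "re_per_atom": 0.160157, "sd": 5.65958},
    "ZHCF(4)": {"e_pi": 3038.259, "gap": 0.61518, "e_pi_per_atom": 1.489,
                "deloc_per_atom": 0.489343, "re_per_atom": 0.160615, "sd": 5.66336},
    "AHCF(1)": {"e_pi": 194.662, "gap": 0.7638, "e_pi_per_atom": 1.475,
                "deloc_per_atom": 0.474712, "re_per_atom": 0.156614, "sd": 5.5937},
    "AHCF(2)": {"e_pi": 1337.189, "gap": 0.63774, "e_pi_per_atom": 1.486,
                "deloc_per_atom": 0.485766, "re_per_atom": 0.159636, "sd": 5.65682},
    "AHCF(3)": {"e_pi": 3609.522, "gap": 0.61322, "e_pi_per_atom": 1.489,
                "deloc_per_atom": 0.489077, "re_per_atom": 0.160541, "sd": 5.66408},
    "RCF(1)": {"e_pi": 194.662, "gap": 0.7638, "e_pi_per_atom": 1.475,
               "deloc_per_atom": 0.474712, "re_per_atom": 0.156614, "sd": 5.5937},
    "RCF(2)": {"e_pi": 640.3919, "gap": 0.66974, "e_pi_per_atom": 1.482,
               "deloc_per_atom": 0.482389, "re_per_atom": 0.158714, "sd": 5.64364},
    "RCF(3)": {"e_pi": 1337.19, "gap": 0.6379, "e_pi_per_atom": 1.486,
               "deloc_per_atom": 0.485766, "re_per_atom": 0.159637, "sd": 5.65572},
    "RCF(4)": {"e_pi": 2285.055, "gap": 0.6229, "e_pi_per_atom": 1.488,
               "deloc_per_atom": 0.487666, "re_per_atom": 0.160156, "sd": 5.66072},
}


@dataclass(frozen=True)
class PropertyDataset:
    """Rows of (structure label, descriptor x, property P) for one fit."""

    property_name: str
    descriptor_name: str
    labels: tuple[str, ...]
    x: tuple[float, ...]
    y: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise ValueError("ragged dataset")
        if len(self.x) < 3:
            raise ValueError("need at least 3 rows to fit")
        if not all(math.isfinite(v) for v in self.x + self.y):
            raise ValueError("non-finite value in dataset")


@dataclass(frozen=True)
class RegressionModel:
    """A fitted univariate linear model P = R x + c with its statistics."""

    slope: float
    intercept: float
    r2: float
    adj_r2: float
    se: float       # residual standard error, sqrt(RSS / (n - 2))
    f_stat: float
    n_obs: int
    x_min: float
    x_max: float
    property_name: str = ""
    descriptor_name: str = ""


def fit_linear(ds: PropertyDataset) -> RegressionModel:
    """Ordinary least squares fit of a property against one descriptor."""
    x = np.asarray(ds.x, dtype=float)
    y = np.asarray(ds.y, dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("descriptor has zero variance")
    result = sm.OLS(y, sm.add_constant(x)).fit()
    n = len(x)
    r2 = float(result.rsquared)
    return RegressionModel(
        slope=float(result.params[1]),
        intercept=float(result.params[0]),
        r2=r2,
        adj_r2=1.0 - (1.0 - r2) * (n - 1) / (n - 2),
        se=float(np.sqrt(result.mse_resid)),
        f_stat=float(result.fvalue),
        n_obs=n,
        x_min=float(x.min()),
        x_max=float(x.max()),
        property_name=ds.property_name,
        descriptor_name=ds.descriptor_name,
    )


def _computed_property(s: FractalSpec, prop: str) -> float:
    g = generate(s)
    if prop == "re_per_atom":
        # exact determinant; practical only for the smallest members
        kc = spec_mod.kekule_count(g)
        return spec_mod.resonance_per_atom(kc, g.n_atoms)
    ev = spec_mod.spectrum(g)
    p = g.n_atoms
    if prop == "sd":
        return spec_mod.spectral_diameter(ev)
    if prop == "gap":
        return spec_mod.homo_lumo_gap(ev, p)[2]
    e_pi = spec_mod.total_pi_energy(ev, p)
    if prop == "e_pi":
        return e_pi
    per_atom, deloc = spec_mod.per_atom_energies(e_pi, p)
    return per_atom if prop == "e_pi_per_atom" else deloc


def build_reference_dataset(
    property_name: str, mode: str = "paper"
) -> PropertyDataset:
    """The 11-structure fitting set for one spectral property.

    The descriptor is the raw M2RM1 index for ``e_pi`` and the entropy
    I_M2RM1 for every other property; descriptors are always computed from
    the closed forms.  ``mode`` selects published ("paper") or freshly
    recomputed ("computed") property values.
    """
    if property_name not in PROPERTY_NAMES:
        raise ValueError(
            f"unknown property {property_name!r}; known: {PROPERTY_NAMES}"
        )
    if mode not in ("paper", "computed"):
        raise ValueError("mode must be 'paper' or 'computed'")
    labels, xs, ys = [], [], []
    use_index = property_name == "e_pi"
    for label, s in REFERENCE_STRUCTURES:
        if use_index:
            xs.append(float(index_value_closed_form(s, "M1", k=2)))
        else:
            xs.append(entropy_closed_form(s, "M1", k=2).entropy_bits)
        if mode == "paper":
            ys.append(TABLE_SPECTRA[label][property_name])
        else:
            ys.append(_computed_property(s, property_name))
        labels.append(label)
    return PropertyDataset(
        property_name=property_name,
        descriptor_name="M2RM1" if use_index else "I_M2RM1",
        labels=tuple(labels),
        x=tuple(xs),
        y=tuple(ys),
    )


def predict(model: RegressionModel, x: float) -> float:
    """Evaluate the fitted line at *x*, warning outside the fitted range."""
    if not (model.x_min <= x <= model.x_max):
        warnings.warn(
            f"descriptor value {x} lies outside the fitted range "
            f"[{model.x_min}, {model.x_max}]; this is an extrapolation",
            stacklevel=2,
        )
    return model.slope * x + model.intercept


def fit_reference_models(mode: str = "paper") -> dict[str, RegressionModel]:
    """Fit all six reference property models; keys are property names."""
    return {
        prop: fit_linear(build_reference_dataset(prop, mode=mode))
        for prop in PROPERTY_NAMES
    }
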