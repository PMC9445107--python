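"""Physical constants of PET nuclides and count-statistics matching.

Positron emitters differ in three properties that matter for phantom
imaging: the positron branching fraction (yield), the physical half-life,
and the positron range in water.  The yield and half-life determine how
long one must acquire to collect a given number of true coincidences from
a given activity concentration; the positron range adds a nuclide-specific
blur on top of the scanner's intrinsic point-spread function.  This module
houses a small registry of nuclide constants (F-18, Ga-68, Cu-64 built in,
extensible by the user), the mapping from mean positron range to an
isotropic Gaussian blur kernel, and the closed-form acquisition-duration
matching that equalises expected true counts between nuclides.

The positron-range kernel is parameterised so that its half-width at half
maximum equals the mean positron range in water:

    sigma = R_mean / sqrt(2 ln 2)

The true annihilation-point distribution is cusp-like rather than
Gaussian, but a Gaussian composes analytically with the (Gaussian) system
PSF, which is exactly what the sphere-profile resolution estimator
assumes; see docs/methods.md for the discussion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import yaml

__all__ = [
    "NuclideProps",
    "UnknownNuclideError",
    "UnreachableCountsError",
    "get_nuclide",
    "available_nuclides",
    "register_nuclide",
    "positron_blur_sigma",
    "decay_constant_per_s",
    "expected_trues",
    "matched_acquisition_duration",
]

LN2 = math.log(2.0)
#: FWHM of a Gaussian in units of its standard deviation, 2*sqrt(2 ln 2).
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * LN2)


class UnknownNuclideError(KeyError):
    """Raised when a nuclide name is not present in the registry."""


class UnreachableCountsError(ValueError):
    """Raised when the requested true-count total cannot be reached even
    after complete decay of the activity."""


@dataclass(frozen=True)
class NuclideProps:
    """Physical constants of a positron-emitting nuclide.

    Parameters
    ----------
    name : str
        Canonical identifier, e.g. ``"F18"``.
    beta_yield : float
        Positron branching fraction in (0, 1].
    half_life_min : float
        Physical half-life in minutes.
    e_max_kev, e_mean_kev : float
        Maximum (endpoint) and average beta+ energy in keV.
    range_max_water_mm, range_mean_water_mm : float
        Maximum and mean positron range in water in mm.
    """

    name: str
    beta_yield: float
    half_life_min: float
    e_max_kev: float
    e_mean_kev: float
    range_max_water_mm: float
    range_mean_water_mm: float

    def __post_init__(self) -> None:
        if not (0.0 < self.beta_yield <= 1.0):
            raise ValueError(f"beta_yield must be in (0, 1], got {self.beta_yield}")
        if self.half_life_min <= 0.0:
            raise ValueError(f"half_life_min must be > 0, got {self.half_life_min}")
        if not (self.e_mean_kev < self.e_max_kev):
            raise ValueError("e_mean_kev must be smaller than e_max_kev")
        if self.range_mean_water_mm < 0 or self.range_max_water_mm < 0:
            raise ValueError("positron ranges must be nonnegative")
        if self.range_mean_water_mm >= self.range_max_water_mm:
            raise ValueError("range_mean_water_mm must be smaller than range_max_water_mm")


_REGISTRY: dict[str, NuclideProps] = {}


def _canonical(name: str) -> str:
    """Normalise a nuclide name: 'f-18', '18F' and 'F18' all map to 'f18'."""
    s = "".join(ch for ch in name if ch.isalnum()).lower()
    # allow mass-number-first spellings like "18f"
    i = 0
    while i < len(s) and s[i].isdigit():
        i += 1
    if 0 < i < len(s):
        s = s[i:] + s[:i]
    return s


def register_nuclide(props: NuclideProps, overwrite: bool = False) -> None:
    """Add a nuclide to the registry (merge-by-name for user extensions)."""
    key = _canonical(props.name)
    if key in _REGISTRY and not overwrite:
        raise ValueError(f"nuclide {props.name!r} already registered; pass overwrite=True")
    _REGISTRY[key] = props


def _load_builtin() -> None:
    text = resources.files("phantomiq.data").joinpath("nuclides.yaml").read_text()
    table = yaml.safe_load(text)["nuclides"]
    for name, row in table.items():
        register_nuclide(NuclideProps(name=name, **row), overwrite=True)


_load_builtin()


def available_nuclides() -> tuple[str, ...]:
    """Canonical names of all registered nuclides."""
    return tuple(sorted(p.name for p in _REGISTRY.values()))


def get_nuclide(name: str) -> NuclideProps:
    """Look up a nuclide by name (case- and punctuation-insensitive).

    Raises
    ------
    UnknownNuclideError
        If the name is not registered; the message lists valid options.
    """
    try:
        return _REGISTRY[_canonical(name)]
    except KeyError:
        raise UnknownNuclideError(
            f"unknown nuclide {name!r}; registered nuclides: {', '.join(available_nuclides())}"
        ) from None


def positron_blur_sigma(nuclide: NuclideProps, model: str = "gaussian_mean_range") -> float:
    """Standard deviation (mm) of the isotropic Gaussian positron-range kernel.

    Under the ``gaussian_mean_range`` model the kernel's half-width at half
    maximum equals the nuclide's mean positron range in water, i.e.
    ``sigma = range_mean_water_mm / sqrt(2 ln 2)``.  Deterministic and
    strictly increasing in the mean range.
    """
    if model != "gaussian_mean_range":
        raise ValueError(f"unsupported positron-range kernel model: {model!r}")
    return nuclide.range_mean_water_mm / math.sqrt(2.0 * LN2)


def decay_constant_per_s(nuclide: NuclideProps) -> float:
    """Decay constant lambda = ln2 / T_half in 1/s."""
    return LN2 / (nuclide.half_life_min * 60.0)


def expected_trues(nuclide: NuclideProps, activity_conc: float, duration_s: float) -> float:
    """Expected true counts (per unit volume, arbitrary proportionality).

    Decay during the acquisition is integrated continuously:

        N(T) = yield * A0 * (1 - exp(-lambda T)) / lambda

    with ``A0`` the activity concentration at scan start (kBq/mL) and
    ``lambda`` in 1/s, so the result scales like kBq*s/mL.  Only ratios of
    this quantity between nuclides are meaningful.
    """
    if activity_conc <= 0 or duration_s <= 0:
        raise ValueError("activity concentration and duration must be > 0")
    lam = decay_constant_per_s(nuclide)
    return nuclide.beta_yield * activity_conc * (-math.expm1(-lam * duration_s)) / lam


def matched_acquisition_duration(
    nuclide: NuclideProps,
    activity_conc_at_start: float,
    reference_nuclide: NuclideProps,
    reference_conc: float,
    reference_duration_s: float,
) -> float:
    """Acquisition duration (s) matching the reference's expected trues.

    Solves ``expected_trues(nuclide, A0, T) == expected_trues(reference,
    A_ref, T_ref)`` for ``T``.  The equation is monotone in ``T`` and has
    the closed form ``T = -log(1 - lambda K / (yield A0)) / lambda`` with
    ``K`` the reference's integrated-yield constant.

    Raises
    ------
    UnreachableCountsError
        If the reference count total exceeds what the target nuclide can
        deliver before complete decay (``lambda K >= yield * A0``).
    """
    if activity_conc_at_start <= 0:
        raise ValueError("activity_conc_at_start must be > 0")
    k = expected_trues(reference_nuclide, reference_conc, reference_duration_s)
    lam = decay_constant_per_s(nuclide)
    x = lam * k / (nuclide.beta_yield * activity_conc_at_start)
    if x >= 1.0:
        raise UnreachableCountsError(
            f"target of {k:.4g} integrated trues unreachable for {nuclide.name}: "
            f"complete decay of {activity_conc_at_start} kBq/mL yields only "
            f"{nuclide.beta_yield * activity_conc_at_start / lam:.4g}"
        )
    return -math.log1p(-x) / lam
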