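"""Synthetic metaphase score tables with the assay's statistical structure.

The generator emulates the dicentric-assay study design this package
analyzes: blood lymphocytes irradiated at 0, 0.5, 1, 2 and 4 Gy, two
slides of ~100 metaphases scored per dose (200 cells/dose), per-cell
aberration counts Poisson-distributed at each dose with the option of
mild overdispersion at 4 Gy, and group-specific linear-quadratic yields.

Group presets carry the published calibration coefficients for four donor
cohorts (African ancestry living in Africa — Senegal alone and the pooled
multi-country cohort — African ancestry living in Europe, and Caucasians
living in Europe). The publication reports yields for three endpoints
(dicentrics; dicentrics + rings; reconstructed DSB) but no class-wise
breakdown, so the presets derive:

* the centric-ring yield as (dicentrics+rings) minus (dicentrics),
  floored at 0 componentwise;
* the residual DSB yield as (DSB) minus 2 x (dicentrics+rings), split
  50/25/25 (in DSB units) between terminal deletions, interstitial
  deletions and telomere deletions.

Backgrounds: African donors showed no spontaneous dicentrics in 12,450
cells (C = 0) with a small residual DSB background of 0.17% per cell;
Caucasian donors showed 6 dicentrics in 5,200 cells (C = 6/5200).

Each dicentric or centric ring is accompanied by one four-telomere
acentric fragment, mirroring the scoring rule that pairs them; an
independence mode is available for stress testing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import yaml

from .aberration_core import AberrationTally, MetaphaseRecord
from .dose_response import DoseResponseCurve

__all__ = [
    "LQYield",
    "CohortSpec",
    "REFERENCE_COEFFICIENTS",
    "GROUP_PRESETS",
    "group_preset",
    "make_cohort_spec",
    "reference_curve",
    "simulate_cohort",
    "simulate_tallies",
    "simulate_background",
    "spec_to_yaml",
    "spec_from_yaml",
]

DEFAULT_DOSES = (0.0, 0.5, 1.0, 2.0, 4.0)
DEFAULT_CELLS_PER_DOSE = 200  # two slides x ~100 metaphases
#: Residual (non-dicentric, non-ring) background, DSB per cell at 0 Gy.
BACKGROUND_RESIDUAL_DSB = 0.0017
#: Spontaneous dicentric yield per cell in the Caucasian cohort (6/5,200).
CAUCASIAN_BACKGROUND_DIC = 6 / 5200

#: Published linear-quadratic coefficients per donor group and endpoint:
#: (alpha, se_alpha, beta, se_beta, printed alpha/beta, cov(alpha, beta)).
REFERENCE_COEFFICIENTS: dict[str, dict[str, dict[str, float]]] = {
    "senegal_africa": {
        "dicentrics": dict(alpha=0.168, se_alpha=0.018, beta=0.061, se_beta=0.006,
                           ratio=2.75, cov_alpha_beta=-0.0001),
        "dicentrics_rings": dict(alpha=0.207, se_alpha=0.065, beta=0.065, se_beta=0.008,
                                 ratio=3.18, cov_alpha_beta=-0.0002),
        "dsb": dict(alpha=0.512, se_alpha=0.050, beta=0.155, se_beta=0.016,
                    ratio=3.30, cov_alpha_beta=-0.0007),
    },
    "all_african": {
        "dicentrics": dict(alpha=0.103, se_alpha=0.008, beta=0.079, se_beta=0.002,
                           ratio=1.30, cov_alpha_beta=-2.2e-5),
        "dicentrics_rings": dict(alpha=0.107, se_alpha=0.010, beta=0.102, se_beta=0.003,
                                 ratio=1.04, cov_alpha_beta=-3e-5),
        "dsb": dict(alpha=0.263, se_alpha=0.026, beta=0.257, se_beta=0.009,
                    ratio=1.02, cov_alpha_beta=-0.0024),
    },
    "senegal_europe": {
        "dicentrics": dict(alpha=0.084, se_alpha=0.022, beta=0.122, se_beta=0.007,
                           ratio=0.68, cov_alpha_beta=-0.0001),
        "dicentrics_rings": dict(alpha=0.083, se_alpha=0.034, beta=0.146, se_beta=0.011,
                                 ratio=0.56, cov_alpha_beta=-0.0003),
        "dsb": dict(alpha=0.219, se_alpha=0.111, beta=0.357, se_beta=0.369,
                    ratio=0.61, cov_alpha_beta=-0.0038),
    },
    "caucasian_europe": {
        "dicentrics": dict(alpha=0.147, se_alpha=0.040, beta=0.128, se_beta=0.013,
                           ratio=1.14, cov_alpha_beta=-0.0005),
        "dicentrics_rings": dict(alpha=0.120, se_alpha=0.043, beta=0.171, se_beta=0.013,
                                 ratio=0.70, cov_alpha_beta=-0.0005),
        "dsb": dict(alpha=0.277, se_alpha=0.091, beta=0.257, se_beta=0.009,
                    ratio=1.07, cov_alpha_beta=-0.0002),
    },
}

SIMULATED_CLASSES = ("dic", "cring", "aring", "ace_2tel", "ace_0tel", "teldel")

_CLASS_TO_ATTR = {
    "dic": "n_dicentric",
    "cring": "n_centric_ring",
    "aring": "n_acentric_ring",
    "ace_4tel": "n_ace_4tel",
    "ace_2tel": "n_ace_2tel",
    "ace_0tel": "n_ace_0tel",
    "teldel": "n_tel_deletion",
}


@dataclass(frozen=True)
class LQYield:
    """Per-cell linear-quadratic yield C + alpha*D + beta*D^2 for one class."""

    C: float = 0.0
    alpha: float = 0.0
    beta: float = 0.0

    def at(self, dose_gy: float) -> float:
        return self.C + self.alpha * dose_gy + self.beta * dose_gy**2


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate one scored cohort reproducibly."""

    group_id: str
    class_yields: Mapping[str, LQYield]
    doses: tuple[float, ...] = DEFAULT_DOSES
    cells_per_dose: int = DEFAULT_CELLS_PER_DOSE
    #: 1 = Poisson; > 1 = gamma-mixed Poisson with variance = dispersion * mean.
    #: A mapping gives per-dose values ("default" key for unlisted doses).
    dispersion: float | Mapping[float | str, float] = 1.0
    seed: int = 0
    #: One 4-telomere fragment accompanies each dicentric/centric ring when
    #: True; when False ace_4tel is drawn independently at the same mean.
    couple_fragments: bool = True
    non_analyzable_fraction: float = 0.0
    n_donors: int = 1
    donor_frailty_sigma: float = 0.0  # lognormal yield multiplier, mean 1

    def __post_init__(self) -> None:
        if self.cells_per_dose < 1:
            raise ValueError("cells_per_dose must be >= 1")
        if not 0.0 <= self.non_analyzable_fraction < 1.0:
            raise ValueError("non_analyzable_fraction must lie in [0, 1)")
        if self.n_donors < 1:
            raise ValueError("n_donors must be >= 1")
        for name, ly in self.class_yields.items():
            if name not in SIMULATED_CLASSES and name != "ace_4tel":
                raise ValueError(f"unknown aberration class {name!r}")
            for d in self.doses:
                if d < 0:
                    raise ValueError(f"negative dose {d}")
                if ly.at(d) < 0:
                    raise ValueError(
                        f"class {name!r} has negative yield {ly.at(d):.4g} at {d} Gy"
                    )

    def dispersion_at(self, dose_gy: float) -> float:
        if isinstance(self.dispersion, Mapping):
            val = self.dispersion.get(dose_gy, self.dispersion.get("default", 1.0))
        else:
            val = float(self.dispersion)
        if val < 1.0:
            raise ValueError(f"dispersion must be >= 1, got {val} at {dose_gy} Gy")
        return val


def _split_residual_dsb(r_C: float, r_alpha: float, r_beta: float,
                        fractions: tuple[float, float, float]) -> dict[str, LQYield]:
    """Allocate a residual DSB yield to terminal/interstitial/telomere deletions.

    Fractions are in DSB units; interstitial deletions carry 2 DSB each so
    their fragment yield is half their DSB share.
    """
    f2, f0, ft = fractions
    comp = (max(r_C, 0.0), max(r_alpha, 0.0), max(r_beta, 0.0))
    return {
        "ace_2tel": LQYield(*(f2 * c for c in comp)),
        "ace_0tel": LQYield(*(f0 * c / 2.0 for c in comp)),
        "teldel": LQYield(*(ft * c for c in comp)),
    }


def group_preset(
    name: str, residual_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
) -> dict[str, LQYield]:
    """Class-wise LQ yields for a named donor group.

    Dicentric coefficients equal the published values exactly; ring and
    deletion-class yields are derived as described in the module docstring.
    """
    if name not in REFERENCE_COEFFICIENTS:
        raise KeyError(
            f"unknown preset {name!r}; available: {sorted(REFERENCE_COEFFICIENTS)}"
        )
    coef = REFERENCE_COEFFICIENTS[name]
    dic = coef["dicentrics"]
    dicring = coef["dicentrics_rings"]
    dsb = coef["dsb"]
    c_dic = CAUCASIAN_BACKGROUND_DIC if name == "caucasian_europe" else 0.0
    yields: dict[str, LQYield] = {
        "dic": LQYield(c_dic, dic["alpha"], dic["beta"]),
        "cring": LQYield(
            0.0,
            max(dicring["alpha"] - dic["alpha"], 0.0),
            max(dicring["beta"] - dic["beta"], 0.0),
        ),
        "aring": LQYield(),
    }
    residual_alpha = dsb["alpha"] - 2.0 * dicring["alpha"]
    residual_beta = dsb["beta"] - 2.0 * dicring["beta"]
    yields.update(
        _split_residual_dsb(
            BACKGROUND_RESIDUAL_DSB, residual_alpha, residual_beta, residual_fractions
        )
    )
    return yields


def make_cohort_spec(
    preset: str,
    cells_per_dose: int = DEFAULT_CELLS_PER_DOSE,
    doses: Sequence[float] = DEFAULT_DOSES,
    seed: int = 0,
    dispersion: float | Mapping[float | str, float] | None = None,
    **overrides,
) -> CohortSpec:
    """CohortSpec for a named group preset under the study's design.

    The default dispersion is Poisson at every dose with a mild
    overdispersion of 1.3 at 4 Gy, matching the only dose at which the
    assay departed from Poisson.
    """
    if dispersion is None:
        dispersion = {"default": 1.0, 4.0: 1.3}
    return CohortSpec(
        group_id=preset,
        class_yields=group_preset(preset),
        doses=tuple(float(d) for d in doses),
        cells_per_dose=cells_per_dose,
        dispersion=dispersion,
        seed=seed,
        **overrides,
    )


def reference_curve(group: str, endpoint: str) -> DoseResponseCurve:
    """A DoseResponseCurve carrying the published coefficients for a group.

    C is the preset background for the endpoint (0 for African groups'
    dicentrics). The (alpha, beta) covariance block comes from the
    published SEs and covariance; se_C is 0 (background treated as known).
    Some published covariances exceed the product of the printed SEs, so
    not every reference block is positive semi-definite; those curves
    serve ratio and contrast checks, not envelope propagation.
    """
    coef = REFERENCE_COEFFICIENTS[group][endpoint]
    c_dic = CAUCASIAN_BACKGROUND_DIC if group == "caucasian_europe" else 0.0
    if endpoint == "dicentrics" or endpoint == "dicentrics_rings":
        c0 = c_dic
    else:
        c0 = 2.0 * c_dic + BACKGROUND_RESIDUAL_DSB
    vcov = np.zeros((3, 3))
    vcov[1, 1] = coef["se_alpha"] ** 2
    vcov[2, 2] = coef["se_beta"] ** 2
    vcov[1, 2] = vcov[2, 1] = coef["cov_alpha_beta"]
    return DoseResponseCurve(
        endpoint=endpoint,
        C=c0,
        alpha=coef["alpha"],
        beta=coef["beta"],
        se_C=0.0,
        se_alpha=coef["se_alpha"],
        se_beta=coef["se_beta"],
        vcov=vcov,
        dispersion_scale=1.0,
        n_points=0,
    )


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------


def _draw_counts(
    rng: np.random.Generator, lam: np.ndarray, dispersion: float
) -> np.ndarray:
    """Per-cell counts with mean lam and variance dispersion * lam.

    dispersion = 1 is plain Poisson; above 1, a gamma-mixed Poisson
    (negative binomial) with shape lam/(dispersion-1) and scale
    dispersion-1 gives the requested variance inflation.
    """
    lam = np.asarray(lam, dtype=float)
    out = np.zeros(lam.shape, dtype=np.int64)
    pos = lam > 0
    if not pos.any():
        return out
    if dispersion <= 1.0:
        out[pos] = rng.poisson(lam[pos])
    else:
        scale = dispersion - 1.0
        mixed = rng.gamma(shape=lam[pos] / scale, scale=scale)
        out[pos] = rng.poisson(mixed)
    return out


def _simulate_dose(
    rng: np.random.Generator, spec: CohortSpec, dose: float, frailty: np.ndarray
) -> dict[str, np.ndarray]:
    """Raw per-cell count arrays for one dose (plus centromere counts)."""
    n = spec.cells_per_dose
    disp = spec.dispersion_at(dose)
    donor_idx = np.arange(n) % spec.n_donors
    mult = frailty[donor_idx]
    counts: dict[str, np.ndarray] = {}
    for cls in SIMULATED_CLASSES:
        ly = spec.class_yields.get(cls, LQYield())
        counts[cls] = _draw_counts(rng, ly.at(dose) * mult, disp)
    if spec.couple_fragments:
        counts["ace_4tel"] = counts["dic"] + counts["cring"]
    else:
        lam4 = (
            spec.class_yields.get("dic", LQYield()).at(dose)
            + spec.class_yields.get("cring", LQYield()).at(dose)
        ) * mult
        counts["ace_4tel"] = _draw_counts(rng, lam4, disp)
    centromeres = np.full(n, 46, dtype=np.int64)
    if spec.non_analyzable_fraction > 0:
        bad = rng.random(n) < spec.non_analyzable_fraction
        centromeres[bad] = rng.choice([44, 45, 47], size=int(bad.sum()))
    counts["_centromeres"] = centromeres
    counts["_donor_idx"] = donor_idx
    return counts


def _frailty(rng: np.random.Generator, spec: CohortSpec) -> np.ndarray:
    if spec.donor_frailty_sigma > 0:
        s = spec.donor_frailty_sigma
        return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=spec.n_donors)
    return np.ones(spec.n_donors)


def simulate_cohort(spec: CohortSpec) -> list[MetaphaseRecord]:
    """Per-metaphase records for every dose in the spec. Seed-deterministic."""
    rng = np.random.default_rng(spec.seed)
    frailty = _frailty(rng, spec)
    records: list[MetaphaseRecord] = []
    for dose in spec.doses:
        arrays = _simulate_dose(rng, spec, dose, frailty)
        for i in range(spec.cells_per_dose):
            records.append(
                MetaphaseRecord(
                    donor_id=f"{spec.group_id}-d{int(arrays['_donor_idx'][i]) + 1}",
                    group_id=spec.group_id,
                    dose_gy=dose,
                    centromere_count=int(arrays["_centromeres"][i]),
                    **{
                        attr: int(arrays[cls][i])
                        for cls, attr in _CLASS_TO_ATTR.items()
                    },
                )
            )
    return records


def simulate_tallies(spec: CohortSpec) -> list[AberrationTally]:
    """Per-dose tallies over analyzable cells, drawn as in simulate_cohort.

    Fast path for large simulations: identical draws, summed without
    materializing per-cell records.
    """
    rng = np.random.default_rng(spec.seed)
    frailty = _frailty(rng, spec)
    tallies = []
    for dose in spec.doses:
        arrays = _simulate_dose(rng, spec, dose, frailty)
        ok = arrays["_centromeres"] == 46
        if not ok.any():
            raise ValueError(f"no analyzable cells simulated at {dose} Gy")
        tallies.append(
            AberrationTally(
                group_id=spec.group_id,
                dose_gy=dose,
                n_cells=int(ok.sum()),
                **{
                    attr: int(arrays[cls][ok].sum())
                    for cls, attr in _CLASS_TO_ATTR.items()
                },
            )
        )
    return tallies


def simulate_background(spec: CohortSpec) -> list[MetaphaseRecord]:
    """Zero-dose records; expected dicentric total is n_cells * C_dic."""
    if tuple(spec.doses) != (0.0,):
        spec = dataclasses.replace(spec, doses=(0.0,))
    return simulate_cohort(spec)


# ---------------------------------------------------------------------------
# YAML round trip for cohort specs
# ---------------------------------------------------------------------------


def spec_to_yaml(spec: CohortSpec) -> str:
    payload = dataclasses.asdict(spec)
    payload["class_yields"] = {
        k: dataclasses.asdict(v) if isinstance(v, LQYield) else dict(v)
        for k, v in spec.class_yields.items()
    }
    payload["doses"] = list(spec.doses)
    if isinstance(spec.dispersion, Mapping):
        payload["dispersion"] = {k: v for k, v in spec.dispersion.items()}
    return yaml.safe_dump(payload, sort_keys=False)


def spec_from_yaml(text: str) -> CohortSpec:
    payload = yaml.safe_load(text)
    payload["class_yields"] = {
        k: LQYield(**v) for k, v in payload["class_yields"].items()
    }
    payload["doses"] = tuple(float(d) for d in payload["doses"])
    return CohortSpec(**payload)
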