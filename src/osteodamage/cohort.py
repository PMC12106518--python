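"""Synthetic cohort generator emulating the study design.

Emulates two test series on human-rib cortical bone: quasi-static uniaxial
tension on machined coupons (default 51 specimens, ages 55 +/- 20 years
truncated to [21, 91], 35 male / 16 female) and three-point bending of
whole ribs reduced to a prismatic beam (default 15 specimens, ages
55 +/- 11 truncated to [26, 62], 10 male / 5 female).

Each specimen's constitutive parameters are drawn around cohort base
values with three latent factors driving the ten identifiable parameters
(communality ~0.8, so a 3-component PCA of the cohort parameter matrix
recovers most of the variance). The first factor is standardized age, and
the quenched-disorder parameter additionally follows an explicit positive
age slope (older bone carries more initial microcracking and responds
more weakly), plus specimen-level noise. Curves are simulated with the
plane-stress drivers up to a damage stopping level and perturbed with
multiplicative measurement noise (~1% CV by default). The manifest keeps
the hidden ground truth for recovery experiments; sex is assigned but has
no generative effect (no such link is modelled).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import REDUCED_FIELDS, expand_reduced
from .curves import CurveTable, write_curve
from .errors import ValidationError
from .material_point import SectionSpec, bending_response, strain_at_alpha, uniaxial_monotonic

#: latent-factor loadings (rows: generated parameters, columns: 3 factors;
#: factor 1 is standardized age). Rows are normalized at import time.
_LOADINGS = {
    "a2":      (0.50, 0.87, 0.00),
    "b2":      (0.50, 0.80, 0.33),
    "rho_tau2": (0.45, 0.89, 0.00),
    "mu3":     (0.50, 0.00, 0.87),
    "nu3":     (0.40, 0.20, 0.89),
    "sigma3":  (0.30, 0.30, 0.90),
    "rho_tau3": (0.55, 0.00, 0.84),
    "r":       (0.30, 0.60, 0.74),
    "eps0":    (0.60, 0.40, 0.69),
}
#: log-scale dispersion per generated parameter
_LOG_SD = {
    "a2": 0.12, "b2": 0.12, "rho_tau2": 0.12,
    "mu3": 0.18, "nu3": 0.25, "sigma3": 0.25, "rho_tau3": 0.18,
    "r": 0.08, "eps0": 0.12,
}
#: cohort base values (a2 = mu2 + nu2/2, b2 = -nu2/2 keep the sign
#: constraints satisfied for any positive multiplicative draw)
_BASE = {
    "a2": 800.0, "b2": 1000.0, "rho_tau2": 1000.0,
    "mu3": -5000.0, "nu3": -2000.0, "sigma3": -1000.0, "rho_tau3": -60000.0,
    "r": 2.0, "eps0": 0.004,
}
_COMMUNALITY = 0.8
_N_FIXED = 4


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters of the synthetic cohort."""

    n_tensile: int = 51
    n_bending: int = 15
    age_mean_tensile: float = 55.0
    age_sd_tensile: float = 20.0
    age_range_tensile: tuple = (21.0, 91.0)
    age_mean_bending: float = 55.0
    age_sd_bending: float = 11.0
    age_range_bending: tuple = (26.0, 62.0)
    beta0: float = 0.4              # 1/MPa at age 55
    beta_age_slope: float = 0.006   # 1/MPa per year, positive (aging weakens)
    beta_noise_sd: float = 0.08     # 1/MPa specimen-level scatter
    noise_cv: float = 0.01          # multiplicative measurement noise
    alpha_max: float = 0.5          # driver stopping damage level
    n_points: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tensile < 1 or self.n_bending < 0:
            raise ValidationError("cohort counts must be positive")
        if self.noise_cv < 0.0:
            raise ValidationError("noise_cv must be nonnegative")
        if self.beta_age_slope <= 0.0:
            raise ValidationError("beta_age_slope must be positive")

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc = {k: (tuple(v) if isinstance(v, list) else v) for k, v in doc.items()}
        try:
            return cls(**doc)
        except TypeError as exc:
            raise ValidationError(f"bad cohort spec {path}: {exc}") from exc

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


@dataclass
class SpecimenRecord:
    """One synthetic specimen with its hidden ground truth."""

    id: str
    age: float
    sex: str
    test_type: str
    true_params: dict       # reduced parameter vector + N
    curve: CurveTable
    curve_file: str | None = None


def _truncated_normal(rng, mean, sd, lo, hi) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValidationError("truncated normal draw failed (bounds too tight)")


def _draw_reduced(rng, z: np.ndarray) -> dict:
    """One multiplicative factor-model draw of the generated parameters."""
    out = {}
    for name, base in _BASE.items():
        u = np.asarray(_LOADINGS[name], dtype=float)
        u = u / np.linalg.norm(u)
        shared = float(u @ z)
        idio = rng.normal()
        dev = _LOG_SD[name] * (
            np.sqrt(_COMMUNALITY) * shared + np.sqrt(1.0 - _COMMUNALITY) * idio
        )
        out[name] = base * float(np.exp(dev))
    return out


def _specimen_params(rng, age: float, age_mean: float, age_sd: float, spec: CohortSpec) -> dict:
    """Draw a valid reduced parameter vector for one specimen (redraws on
    constraint violation, at most 100 attempts)."""
    z_age = (age - age_mean) / age_sd
    for _ in range(100):
        z = np.array([z_age, rng.normal(), rng.normal()])
        raw = _draw_reduced(rng, z)
        beta = spec.beta0 + spec.beta_age_slope * (age - age_mean) + rng.normal(0.0, spec.beta_noise_sd)
        if beta <= 0.02:
            continue
        reduced = {
            "mu2": raw["a2"] + raw["b2"], "nu2": -2.0 * raw["b2"],
            "rho_tau2": raw["rho_tau2"],
            "mu3": raw["mu3"], "nu3": raw["nu3"], "sigma3": raw["sigma3"],
            "rho_tau3": raw["rho_tau3"],
            "beta": float(beta), "r": raw["r"], "eps0": raw["eps0"],
        }
        if not (1.0 < reduced["r"] <= 3.0):
            continue
        try:
            expand_reduced(reduced, _N_FIXED)
        except ValidationError:
            continue
        reduced["N"] = _N_FIXED
        return reduced
    raise ValidationError("could not draw valid specimen parameters in 100 attempts")


def _sexes(rng, n: int, male_frac: float) -> list[str]:
    males = int(round(n * male_frac))
    labels = ["M"] * males + ["F"] * (n - males)
    rng.shuffle(labels)
    return labels


def _noisy(rng, values: np.ndarray, cv: float) -> np.ndarray:
    out = values.copy()
    if cv > 0.0 and len(values) > 1:
        out[1:] = values[1:] * np.exp(rng.normal(0.0, cv, size=len(values) - 1))
    return out


def generate_cohort(
    spec: CohortSpec | None = None,
    out_dir=None,
    section: SectionSpec | None = None,
) -> tuple[list[SpecimenRecord], dict]:
    """Generate the synthetic cohort; returns (records, manifest).

    Deterministic under ``spec.seed``: the same seed reproduces a
    byte-identical manifest. With ``out_dir`` set, curves are written as
    CSV (+ metadata sidecars) and the manifest as ``manifest.json``.
    """
    spec = spec or CohortSpec()
    section = section or SectionSpec()
    rng = np.random.default_rng(spec.seed)
    records: list[SpecimenRecord] = []

    sexes_t = _sexes(rng, spec.n_tensile, 35.0 / 51.0)
    sexes_b = _sexes(rng, spec.n_bending, 10.0 / 15.0)

    for i in range(spec.n_tensile):
        age = _truncated_normal(rng, spec.age_mean_tensile, spec.age_sd_tensile,
                                *spec.age_range_tensile)
        reduced = _specimen_params(rng, age, spec.age_mean_tensile, spec.age_sd_tensile, spec)
        theta = expand_reduced({k: reduced[k] for k in REDUCED_FIELDS}, reduced["N"])
        e_max = strain_at_alpha(theta, spec.alpha_max)
        grid = np.linspace(0.0, e_max, spec.n_points)
        resp = uniaxial_monotonic(grid, theta)
        sid = f"T{i + 1:03d}"
        meta = {"specimen_id": sid, "test_type": "tension",
                "age": round(age, 2), "sex": sexes_t[i]}
        curve = CurveTable(grid, _noisy(rng, resp.sigma, spec.noise_cv), "tension", meta)
        records.append(SpecimenRecord(sid, age, sexes_t[i], "tension", reduced, curve))

    half_t = section.thickness / 2.0
    for i in range(spec.n_bending):
        age = _truncated_normal(rng, spec.age_mean_bending, spec.age_sd_bending,
                                *spec.age_range_bending)
        reduced = _specimen_params(rng, age, spec.age_mean_bending, spec.age_sd_bending, spec)
        theta = expand_reduced({k: reduced[k] for k in REDUCED_FIELDS}, reduced["N"])
        kappa_max = strain_at_alpha(theta, spec.alpha_max) / half_t
        grid = np.linspace(0.0, kappa_max, spec.n_points)
        curve = bending_response(section, grid, theta)
        sid = f"B{i + 1:03d}"
        curve.metadata.update({"specimen_id": sid, "age": round(age, 2),
                               "sex": sexes_b[i],
                               "section": {"width": section.width,
                                           "thickness": section.thickness,
                                           "layers": section.layers,
                                           "span": section.span}})
        curve.ordinate = _noisy(rng, curve.ordinate, spec.noise_cv)
        records.append(SpecimenRecord(sid, age, sexes_b[i], "bending", reduced, curve))

    manifest = {
        "spec": asdict(spec),
        "specimens": [
            {
                "id": rec.id, "age": round(rec.age, 6), "sex": rec.sex,
                "test_type": rec.test_type,
                "curve_file": f"{rec.id}.csv",
                "true_params": {k: (v if k == "N" else float(v))
                                for k, v in rec.true_params.items()},
            }
            for rec in records
        ],
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec in records:
            path = out / f"{rec.id}.csv"
            write_curve(rec.curve, path)
            rec.curve_file = str(path)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )
    return records, manifest


def parameter_matrix(manifest: dict, test_type: str | None = "tension") -> pd.DataFrame:
    """Specimens x identifiable-parameters table from a cohort manifest."""
    rows, index = [], []
    for entry in manifest["specimens"]:
        if test_type is not None and entry["test_type"] != test_type:
            continue
        rows.append({k: entry["true_params"][k] for k in REDUCED_FIELDS})
        index.append(entry["id"])
    return pd.DataFrame(rows, index=index)


def covariate_table(manifest: dict, test_type: str | None = "tension") -> pd.DataFrame:
    """Age and numerically encoded sex (M=1, F=0) per specimen."""
    rows, index = [], []
    for entry in manifest["specimens"]:
        if test_type is not None and entry["test_type"] != test_type:
            continue
        rows.append({"age": entry["age"], "sex": 1.0 if entry["sex"] == "M" else 0.0})
        index.append(entry["id"])
    return pd.DataFrame(rows, index=index)


def load_manifest(path) -> dict:
    path = Path(path)
    if path.is_dir():
        path = path / "manifest.json"
    if not path.exists():
        raise ValidationError(f"manifest not found: {path}")
    return json.loads(path.read_text())
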