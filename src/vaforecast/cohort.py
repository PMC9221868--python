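"""Seeded synthetic AMD cohort generator.

Emulates the statistical shape of a clinical AMD follow-up registry:
~94 patients contributing one or both eyes (~161 eyes), each eye seen
2-5 times at irregular intervals of roughly two months, with the 22
ETDRS-grid OCT scalars, an anti-VEGF treatment flag, a decimal visual
acuity coupled to retinal state, and a grayscale fundus image whose
geometry encodes the thickness features.

The visual-acuity law is autoregressive: with C0 foveal thickness c_t
(mm), treatment indicator u_t and noise e_t ~ N(0, va_noise_sd),

    VA_{t+1} = clip(VA_t - slope * (c_t - c_base) + effect * u_t + e_t, 0, 1)

so foveal thickening above baseline degrades acuity and an injection
improves it. The pre-noise trajectory and the latent thickness path are
kept in a separate :class:`GroundTruth` object that is never fed to the
models; recovery tests regress on it.
"""

from __future__ import annotations

import datetime as dt
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lxml import etree
from PIL import Image
from scipy import stats

from .records import (
    ZONES,
    ConfigurationError,
    EyeSeries,
    VisitRecord,
)

__all__ = ["CohortConfig", "GroundTruth", "generate_cohort", "render_fundus_image", "write_cohort", "transition_frame"]

C0_BASELINE_MM = 0.27  # healthy-ish foveal average thickness

# ETDRS zone geometry: effective areas (mm^2) used to turn thickness into volume.
_ZONE_AREA = {"C0": 0.785}
_ZONE_AREA.update({z: 1.57 for z in ("N1", "S1", "T1", "I1")})
_ZONE_AREA.update({z: 1.90 for z in ("N2", "S2", "T2", "I2")})

_ZONE_BASE_THICKNESS = {"C0": C0_BASELINE_MM}
_ZONE_BASE_THICKNESS.update({z: 0.32 for z in ("N1", "S1", "T1", "I1")})
_ZONE_BASE_THICKNESS.update({z: 0.29 for z in ("N2", "S2", "T2", "I2")})


@dataclass
class CohortConfig:
    """Study-design knobs of the synthetic cohort."""

    n_patients: int = 94
    p_both_eyes: float = 161.0 / 94.0 - 1.0  # expected eyes ~= 161
    visits_min: int = 2
    visits_max: int = 5
    gap_days_mean: float = 60.0
    gap_days_sd: float = 30.0
    va_noise_sd: float = 0.02
    treatment_effect: float = 0.05  # decimal-VA gain per treated visit
    thickness_va_slope: float = 1.0  # decimal-VA loss per mm of C0 excess thickness
    image_size: int = 64
    noise_salt_pepper_frac: float = 0.02
    seed: int = 0
    p_decline: float = 0.5  # fraction of eyes on a worsening trajectory
    treat_prob: float = 0.4

    def validate(self) -> "CohortConfig":
        if self.n_patients < 1:
            raise ConfigurationError("n_patients must be >= 1")
        if self.visits_min < 2:
            raise ConfigurationError("visits_min must be >= 2 (single-visit series are excluded)")
        if self.visits_max < self.visits_min:
            raise ConfigurationError("visits_max must be >= visits_min")
        for name in ("p_both_eyes", "p_decline", "treat_prob", "noise_salt_pepper_frac"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.gap_days_mean < 14 or self.gap_days_sd < 0:
            raise ConfigurationError("gap distribution invalid (mean >= 14 days, sd >= 0)")
        if self.va_noise_sd < 0:
            raise ConfigurationError("va_noise_sd must be >= 0")
        if self.image_size < 16:
            raise ConfigurationError("image_size must be >= 16")
        return self


@dataclass
class GroundTruth:
    """Latent trajectories of the generator, for recovery tests only."""

    thickness_va_slope: float
    treatment_effect: float
    c0_baseline: float
    eyes: dict[str, dict] = field(default_factory=dict)

    def declining(self, eye_id: str) -> bool:
        return bool(self.eyes[eye_id]["declining"])


def _draw_gaps(rng: np.random.Generator, n: int, mean: float, sd: float) -> np.ndarray:
    """Visit gaps in days from a normal truncated at 14 days."""
    if sd == 0:
        return np.full(n, max(mean, 14.0))
    a = (14.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=n, random_state=rng)


def _generate_eye(
    rng: np.random.Generator, cfg: CohortConfig, patient_id: str, eye: str, start: dt.date
) -> tuple[EyeSeries, dict]:
    n_visits = int(rng.integers(cfg.visits_min, cfg.visits_max + 1))
    gaps = _draw_gaps(rng, n_visits - 1, cfg.gap_days_mean, cfg.gap_days_sd)
    days = np.concatenate([[0.0], np.cumsum(gaps)])
    dates = [start + dt.timedelta(days=int(round(d))) for d in days]

    declining = rng.random() < cfg.p_decline
    drift = rng.uniform(0.010, 0.035) * (1 if declining else -1)
    treated = rng.random(n_visits) < cfg.treat_prob

    # latent foveal thickness path: drift + treatment thinning + AR noise
    c0 = np.empty(n_visits)
    c0[0] = np.clip(C0_BASELINE_MM + rng.normal(0, 0.04), 0.19, 0.50)
    for t in range(1, n_visits):
        step = drift - 0.030 * treated[t - 1] + rng.normal(0, 0.008)
        c0[t] = np.clip(c0[t - 1] + step, 0.18, 0.55)

    va = np.empty(n_visits)
    va_true = np.empty(n_visits)
    # start mid-range so the clip at [0, 1] rarely binds and the VA law
    # stays identifiable from observed transitions
    va[0] = va_true[0] = np.clip(
        0.65 - cfg.thickness_va_slope * (c0[0] - C0_BASELINE_MM) + rng.normal(0, 0.05), 0.05, 0.95
    )
    for t in range(1, n_visits):
        delta = (
            -cfg.thickness_va_slope * (c0[t - 1] - C0_BASELINE_MM)
            + cfg.treatment_effect * treated[t - 1]
        )
        va_true[t] = np.clip(va_true[t - 1] + delta, 0.0, 1.0)
        va[t] = np.clip(va[t - 1] + delta + rng.normal(0, cfg.va_noise_sd), 0.0, 1.0)

    # shared-factor zone model: each zone tracks the foveal deviation (~0.5
    # cross-correlation) plus its own AR(1) wobble
    own = {z: 0.0 for z in ZONES}
    series = EyeSeries(patient_id=patient_id, eye=eye)
    for t in range(n_visits):
        c0_dev = c0[t] - C0_BASELINE_MM
        zone_th, zone_vol = {}, {}
        for z in ZONES:
            own[z] = 0.5 * own[z] + rng.normal(0, 0.012)
            th = _ZONE_BASE_THICKNESS[z] + 0.6 * c0_dev + own[z]
            th = float(np.clip(th, 0.15, 0.60))
            zone_th[z] = th
            zone_vol[z] = float(np.clip(th * _ZONE_AREA[z] + rng.normal(0, 0.01), 0.05, 1.2))
        zone_th["C0"] = float(c0[t])
        zone_vol["C0"] = float(np.clip(c0[t] * _ZONE_AREA["C0"] + rng.normal(0, 0.005), 0.05, 1.2))
        central = float(np.clip(c0[t] + rng.normal(0, 0.004), 0.15, 0.60))
        spread = rng.uniform(0.05, 0.25)
        rec = VisitRecord(
            visit_date=dates[t],
            zone_avg_thickness=zone_th,
            zone_volume=zone_vol,
            central_thickness=central,
            min_central_thickness=central * (1.0 - spread),
            max_central_thickness=central * (1.0 + spread),
            total_volume=float(sum(zone_vol.values())),
            treated=bool(treated[t]),
            va=float(va[t]),
            valid_pixel_percentage={z: 100.0 for z in ZONES},
        )
        series.visits.append(rec)

    truth = {
        "declining": declining,
        "drift": drift,
        "c0_path": c0.tolist(),
        "treated": treated.tolist(),
        "va_true": va_true.tolist(),
    }
    return series, truth


def generate_cohort(config: CohortConfig) -> tuple[list[EyeSeries], GroundTruth]:
    """Generate a seeded cohort of per-eye visit series plus its latent truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    start0 = dt.date(2018, 1, 1)
    cohort: list[EyeSeries] = []
    truth = GroundTruth(
        thickness_va_slope=config.thickness_va_slope,
        treatment_effect=config.treatment_effect,
        c0_baseline=C0_BASELINE_MM,
    )
    for p in range(config.n_patients):
        pid = f"P{p + 1:03d}"
        start = start0 + dt.timedelta(days=int(rng.integers(0, 365)))
        eyes = ["L"] + (["R"] if rng.random() < config.p_both_eyes else [])
        for eye in eyes:
            series, eye_truth = _generate_eye(rng, config, pid, eye, start)
            cohort.append(series)
            truth.eyes[series.eye_id] = eye_truth
    return cohort, truth


def _visit_rng(visit: VisitRecord, config: CohortConfig) -> np.random.Generator:
    """Content-derived RNG so images are a pure function of visit + config."""
    payload = np.round(visit.feature_vector(), 6).tobytes() + bytes([config.seed % 256])
    return np.random.default_rng(zlib.crc32(payload))


def render_fundus_image(visit: VisitRecord, config: CohortConfig) -> np.ndarray:
    """Render an 8-bit grayscale fundus stand-in encoding OCT scalars.

    Geometry: a centred horizontal band whose height is proportional to the
    C0 average thickness, a left vertical stripe whose width follows the N1
    average thickness, and a background level proportional to total volume;
    salt-and-pepper noise at ``noise_salt_pepper_frac``.
    """
    if visit.missing_zones() or visit.central_thickness is None or visit.total_volume is None:
        raise ValueError("render_fundus_image requires all 22 OCT scalars")
    s = config.image_size
    img = np.full((s, s), min(50.0, 10.0 * visit.total_volume))
    c0 = visit.zone_avg_thickness["C0"]
    band = max(1, int(round(s * c0)))  # mm -> fraction of image height
    lo = max(0, s // 2 - band // 2)
    img[lo : min(s, lo + band), :] = 200.0
    n1 = visit.zone_avg_thickness["N1"]
    stripe = max(1, int(round(0.5 * s * n1)))
    img[:, :stripe] = np.maximum(img[:, :stripe], 120.0)
    if config.noise_salt_pepper_frac > 0:
        rng = _visit_rng(visit, config)
        n_bad = int(round(config.noise_salt_pepper_frac * s * s))
        idx = rng.choice(s * s, size=n_bad, replace=False)
        flat = img.reshape(-1)
        flat[idx[: n_bad // 2]] = 0.0
        flat[idx[n_bad // 2 :]] = 255.0
    return img.astype(np.uint8)


_XML_TAGS = {
    "CentralThickness": "central_thickness",
    "MinCentralThickness": "min_central_thickness",
    "MaxCentralThickness": "max_central_thickness",
    "TotalVolume": "total_volume",
}


def _visit_xml(visit: VisitRecord) -> bytes:
    root = etree.Element("OCTReport")
    for tag, attr in _XML_TAGS.items():
        val = getattr(visit, attr)
        if val is not None:
            etree.SubElement(root, tag).text = f"{val:.3f}"
    for z in ZONES:
        th = visit.zone_avg_thickness.get(z)
        vol = visit.zone_volume.get(z)
        if th is None and vol is None:
            continue
        zone = etree.SubElement(root, "Zone")
        etree.SubElement(zone, "Name").text = z
        if th is not None:
            etree.SubElement(zone, "AvgThickness").text = f"{th:.3f}"
        if vol is not None:
            etree.SubElement(zone, "Volume").text = f"{vol:.3f}"
        vpp = visit.valid_pixel_percentage.get(z)
        if vpp is not None:
            etree.SubElement(zone, "ValidPixelPercentage").text = f"{vpp:g}"
    return etree.tostring(root, pretty_print=True)


def write_cohort(
    cohort: list[EyeSeries],
    out_dir: str | Path,
    config: CohortConfig | None = None,
    ground_truth: GroundTruth | None = None,
    write_images: bool = True,
) -> Path:
    """Serialise a cohort as per-visit XML + PNG files plus a CSV visit index."""
    if not cohort:
        raise ValueError("cannot write an empty cohort")
    config = config or CohortConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for series in cohort:
        eye_dir = out / series.eye_id
        eye_dir.mkdir(exist_ok=True)
        for i, visit in enumerate(series.visits, start=1):
            (eye_dir / f"visit_{i:02d}.xml").write_bytes(_visit_xml(visit))
            if write_images:
                img = render_fundus_image(visit, config)
                img_path = eye_dir / f"visit_{i:02d}.png"
                Image.fromarray(img, mode="L").save(img_path)
                visit.image_path = str(img_path)
            rows.append(
                {
                    "patient_id": series.patient_id,
                    "eye": series.eye,
                    "visit_date": visit.visit_date.isoformat(),
                    "va_raw": "" if visit.va is None else f"{visit.va:.3f}",
                    "treated": int(visit.treated),
                }
            )
    pd.DataFrame(rows).to_csv(out / "index.csv", index=False)
    if ground_truth is not None:
        payload = {
            "thickness_va_slope": ground_truth.thickness_va_slope,
            "treatment_effect": ground_truth.treatment_effect,
            "c0_baseline": ground_truth.c0_baseline,
            "eyes": ground_truth.eyes,
        }
        (out / "ground_truth.json").write_text(json.dumps(payload, indent=1))
    if config is not None:
        (out / "cohort_config.json").write_text(json.dumps(asdict(config), indent=1))
    return out


def transition_frame(cohort: list[EyeSeries]) -> pd.DataFrame:
    """All observed (VA_t, C0_t, treated_t) -> VA_{t+1} transitions.

    The regression design for recovering the generator's VA law by ordinary
    least squares: VA_next ~ VA + C0 + treated.
    """
    rows = []
    for series in cohort:
        for prev, nxt in zip(series.visits[:-1], series.visits[1:]):
            if prev.va is None or nxt.va is None:
                continue
            rows.append(
                {
                    "eye_id": series.eye_id,
                    "va": prev.va,
                    "c0": prev.zone_avg_thickness.get("C0"),
                    "treated": float(prev.treated),
                    "va_next": nxt.va,
                }
            )
    return pd.DataFrame(rows)
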