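"""Seeded synthetic cohorts: liver/spleen phantom volumes, masks and
class-conditional serum biomarkers with controllable cirrhosis effect sizes.

Imaging signal for positive cases: high-order Fourier perturbation of the
liver boundary (surface nodularity), a stronger Gaussian-random-field
parenchymal texture, and an enlarged spleen blob.  Sequences can be offset
by a small rigid shift to exercise registration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigurationError
from .preprocess import MriStudy

__all__ = [
    "PhantomParams",
    "PhantomCase",
    "ClinicalPanel",
    "DEFAULT_BIOMARKER_SPEC",
    "generate_cohort",
    "generate_volume",
    "sample_biomarkers",
    "write_cohort",
    "read_cohort",
    "cohort_frame",
]

ANALYTES = ("age", "platelet", "total_bilirubin", "albumin", "ast", "alt",
            "alp", "ggt", "inr")

SEQUENCE_NAMES = ("T1pre", "T2", "PV")

# Class-conditional draws: age is normal (years); the rest are log-normal
# with (mean, sd) given on the log scale.  Directionality: cirrhosis lowers
# platelets and albumin and raises the liver-injury/cholestasis markers and
# INR.  Values are plausibility defaults, not fitted to any cohort.
DEFAULT_BIOMARKER_SPEC: dict[str, dict] = {
    "age": {"dist": "normal", "neg": (50.0, 11.0), "pos": (55.0, 10.0)},
    "platelet": {"dist": "lognormal", "neg": (5.39, 0.25), "pos": (4.66, 0.30)},
    "total_bilirubin": {"dist": "lognormal", "neg": (2.48, 0.32), "pos": (2.94, 0.45)},
    "albumin": {"dist": "lognormal", "neg": (3.76, 0.10), "pos": (3.62, 0.12)},
    "ast": {"dist": "lognormal", "neg": (3.33, 0.38), "pos": (3.91, 0.50)},
    "alt": {"dist": "lognormal", "neg": (3.40, 0.42), "pos": (3.80, 0.55)},
    "alp": {"dist": "lognormal", "neg": (4.36, 0.25), "pos": (4.55, 0.35)},
    "ggt": {"dist": "lognormal", "neg": (3.56, 0.48), "pos": (4.20, 0.60)},
    "inr": {"dist": "lognormal", "neg": (0.02, 0.06), "pos": (0.12, 0.10)},
}


@dataclass
class ClinicalPanel:
    age: float
    platelet: float
    total_bilirubin: float
    albumin: float
    ast: float
    alt: float
    alp: float
    ggt: float
    inr: float

    def __post_init__(self):
        for name in ANALYTES:
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"analyte {name} must be strictly positive")
        if not 18.0 <= self.age <= 100.0:
            raise ConfigurationError("age must lie in [18, 100]")

    def as_dict(self) -> dict[str, float]:
        return {a: float(getattr(self, a)) for a in ANALYTES}


@dataclass
class PhantomParams:
    n_cases: int = 100
    prevalence: float = 0.65
    grid_shape: tuple[int, int, int] = (32, 64, 64)
    nodularity_amp: float = 0.10
    texture_sigma: float = 1.8
    spleen_ratio: float = 1.4
    misalign_max: int = 0
    biomarker_spec: dict = field(default_factory=lambda: DEFAULT_BIOMARKER_SPEC)
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise ConfigurationError("n_cases must be >= 1")
        if not 0.0 <= self.prevalence <= 1.0:
            raise ConfigurationError("prevalence must lie in [0, 1]")
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ConfigurationError("grid_shape axes must all be >= 16")
        if self.nodularity_amp < 0:
            raise ConfigurationError("nodularity_amp must be >= 0")
        if self.texture_sigma < 0:
            raise ConfigurationError("texture_sigma must be >= 0")
        if self.spleen_ratio < 1.0:
            raise ConfigurationError("spleen_ratio must be >= 1")
        if self.misalign_max < 0:
            raise ConfigurationError("misalign_max must be >= 0")
        for analyte in ANALYTES:
            if analyte not in self.biomarker_spec:
                raise ConfigurationError(f"biomarker_spec missing analyte {analyte!r}")
            entry = self.biomarker_spec[analyte]
            for cls in ("neg", "pos"):
                if entry[cls][1] <= 0:
                    raise ConfigurationError(f"biomarker_spec[{analyte!r}][{cls!r}] SD must be > 0")


@dataclass
class PhantomCase:
    case_id: str
    label: int
    stage: int
    study: MriStudy
    panel: ClinicalPanel

    def __post_init__(self):
        if (self.label == 1) != (self.stage == 4):
            raise ConfigurationError("label must be 1 exactly when stage is 4")


# ------------------------------------------------------------------- volumes

# per-sequence tissue intensities (background, liver, spleen)
_TISSUE = {
    "T1pre": (0.08, 0.75, 0.50),
    "T2": (0.10, 0.40, 0.65),
    "PV": (0.08, 0.62, 0.68),
}


def _boundary_radius(theta: np.ndarray, coeffs: list[tuple[int, float, float]]) -> np.ndarray:
    r = np.ones_like(theta)
    for order, amp, phase in coeffs:
        r += amp * np.cos(order * theta + phase)
    return r


def generate_volume(label: int, params: PhantomParams,
                    rng: np.random.Generator, case_id: str = "") -> MriStudy:
    """One multi-sequence study (T1pre, T2, PV) plus the liver mask.

    Positive cases receive the boundary nodularity, stronger parenchymal
    texture and an enlarged spleen; sequences other than the PV reference
    are offset by a uniform integer rigid shift of at most ``misalign_max``
    voxels per axis (recorded in ``meta['misalignment']``).
    """
    params.validate()
    nz, ny, nx = params.grid_shape
    zc, zr = (nz - 1) / 2.0, 0.55 * nz
    cy, cx = 0.48 * ny + rng.normal(0, 1.0), 0.40 * nx + rng.normal(0, 1.0)
    r0 = 0.30 * min(ny, nx) * (1.0 + rng.normal(0, 0.04))

    # smooth per-case shape: low-order Fourier terms
    coeffs = [(k, rng.uniform(0.03, 0.07), rng.uniform(0, 2 * np.pi)) for k in (2, 3)]
    if label == 1 and params.nodularity_amp > 0:
        orders = rng.integers(8, 15, size=4)
        amps = rng.uniform(0.5, 1.0, size=4)
        amps *= params.nodularity_amp / np.sqrt(np.sum(amps**2) / 2)  # rms ~ amp
        coeffs += [(int(k), float(a), rng.uniform(0, 2 * np.pi))
                   for k, a in zip(orders, amps)]

    yy, xx = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    theta = np.arctan2(yy - cy, xx - cx)
    rad = np.hypot(yy - cy, xx - cx)
    rb = _boundary_radius(theta, coeffs)

    mask = np.zeros(params.grid_shape, dtype=np.uint8)
    for z in range(nz):
        zfac = 1.0 - ((z - zc) / zr) ** 2
        if zfac <= 0.05:
            continue
        mask[z] = rad <= r0 * np.sqrt(zfac) * rb

    # spleen blob, upper-contralateral; area scales with spleen_ratio
    sy, sx = 0.30 * ny + rng.normal(0, 1.0), 0.78 * nx + rng.normal(0, 1.0)
    s_ry, s_rx = 0.105 * ny, 0.075 * nx
    if label == 1:
        s_ry *= np.sqrt(params.spleen_ratio)
        s_rx *= np.sqrt(params.spleen_ratio)
    szc, szr = zc + 0.08 * nz, 0.38 * nz
    spleen = np.zeros(params.grid_shape, dtype=bool)
    for z in range(nz):
        zfac = 1.0 - ((z - szc) / szr) ** 2
        if zfac <= 0.05:
            continue
        spleen[z] = (((yy - sy) / (s_ry * np.sqrt(zfac))) ** 2
                     + ((xx - sx) / (s_rx * np.sqrt(zfac))) ** 2) <= 1.0
    spleen &= mask == 0

    # parenchymal texture: unit-variance Gaussian random field, corr. length ~4 vox
    white = rng.normal(0, 1, params.grid_shape)
    grf = ndimage.gaussian_filter(white, sigma=2.0)
    grf /= grf.std() + 1e-12
    tex_scale = 0.035 * (params.texture_sigma if label == 1 else 1.0)

    liver = mask.astype(bool)
    sequences: dict[str, np.ndarray] = {}
    shifts: dict[str, tuple[int, int, int]] = {}
    for seq in SEQUENCE_NAMES:
        bg, lv, sp = _TISSUE[seq]
        vol = np.full(params.grid_shape, bg)
        vol[liver] = lv
        vol[spleen] = sp
        vol[liver] += tex_scale * grf[liver]
        vol += rng.normal(0, 0.02, params.grid_shape)
        if seq != "PV" and params.misalign_max > 0:
            shift = tuple(int(v) for v in rng.integers(-params.misalign_max,
                                                       params.misalign_max + 1, size=3))
        else:
            shift = (0, 0, 0)
        shifts[seq] = shift
        if shift != (0, 0, 0):
            out = np.full_like(vol, bg)
            src = tuple(slice(max(0, -s), n - max(0, s)) for s, n in zip(shift, vol.shape))
            dst = tuple(slice(max(0, s), n - max(0, -s)) for s, n in zip(shift, vol.shape))
            out[dst] = vol[src]
            vol = out
        sequences[seq] = np.clip(vol, 0.0, 1.2).astype(np.float32)

    return MriStudy(sequences=sequences, mask=mask, spacing=(5.0, 1.5, 1.5),
                    case_id=case_id,
                    meta={"label": int(label), "misalignment": shifts, "spleen": spleen})


# ----------------------------------------------------------------- biomarkers


def sample_biomarkers(label: int, spec: dict, rng: np.random.Generator) -> ClinicalPanel:
    """Draw one clinical panel from the class-conditional distributions."""
    for analyte in ANALYTES:
        if analyte not in spec:
            raise ConfigurationError(f"biomarker_spec missing analyte {analyte!r}")
    cls = "pos" if label == 1 else "neg"
    values = {}
    for analyte in ANALYTES:
        entry = spec[analyte]
        m, s = entry[cls]
        if entry.get("dist", "lognormal") == "normal":
            v = rng.normal(m, s)
        else:
            v = float(np.exp(rng.normal(m, s)))
        if analyte == "age":
            v = float(np.clip(v, 18.0, 100.0))
        values[analyte] = max(v, 1e-3)
    return ClinicalPanel(**values)


# --------------------------------------------------------------------- cohort


def _n_positive(prevalence: float, n_cases: int) -> int:
    return int(np.floor(prevalence * n_cases + 0.5))


def generate_cohort(params: PhantomParams) -> list[PhantomCase]:
    """Exactly ``n_cases`` cases with round(prevalence * n) positives,
    labels assigned by stratified shuffling; byte-identical for equal seeds
    (each case derives its stream from (seed, index))."""
    params.validate()
    n_pos = _n_positive(params.prevalence, params.n_cases)
    labels = np.array([1] * n_pos + [0] * (params.n_cases - n_pos))
    np.random.default_rng([params.seed, 0xC0]).shuffle(labels)
    cases = []
    for i, label in enumerate(labels):
        rng = np.random.default_rng([params.seed, i])
        case_id = f"case_{i:04d}"
        study = generate_volume(int(label), params, rng, case_id=case_id)
        panel = sample_biomarkers(int(label), params.biomarker_spec, rng)
        stage = 4 if label == 1 else int(rng.integers(0, 4))
        cases.append(PhantomCase(case_id=case_id, label=int(label), stage=stage,
                                 study=study, panel=panel))
    return cases


def cohort_frame(cases: list[PhantomCase]) -> pd.DataFrame:
    rows = [{"case_id": c.case_id, "label": c.label, "stage": c.stage,
             **c.panel.as_dict()} for c in cases]
    return pd.DataFrame(rows)


# ------------------------------------------------------------------------ I/O

_SUFFIX = {"T1pre": "_t1.nii.gz", "T2": "_t2.nii.gz", "PV": "_pv.nii.gz"}


def write_cohort(cases: list[PhantomCase], out_dir, params: PhantomParams | None = None) -> Path:
    """One NIfTI per sequence and mask per case, a cohort CSV, and a JSON
    manifest listing files, seed and parameters.  Returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for case in cases:
        affine = np.diag([*case.study.spacing, 1.0])
        for seq, vol in case.study.sequences.items():
            path = out_dir / f"{case.case_id}{_SUFFIX[seq]}"
            nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), str(path))
            files.append(path.name)
        mpath = out_dir / f"{case.case_id}_mask.nii.gz"
        nib.save(nib.Nifti1Image(case.study.mask.astype(np.uint8), affine), str(mpath))
        files.append(mpath.name)
    frame = cohort_frame(cases)
    csv_path = out_dir / "cohort.csv"
    frame.to_csv(csv_path, index=False)
    files.append(csv_path.name)
    manifest = {
        "n_cases": len(cases),
        "seed": params.seed if params is not None else None,
        "params": _params_dict(params) if params is not None else None,
        "files": sorted(files),
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def _params_dict(params: PhantomParams) -> dict:
    d = dataclasses.asdict(params)
    d["grid_shape"] = list(d["grid_shape"])
    return d


def read_cohort(cohort_dir) -> tuple[list[MriStudy], pd.DataFrame]:
    """Load studies and the clinical table written by :func:`write_cohort`."""
    cohort_dir = Path(cohort_dir)
    frame = pd.read_csv(cohort_dir / "cohort.csv")
    studies = []
    for case_id in frame["case_id"]:
        sequences = {
            seq: np.asarray(nib.load(str(cohort_dir / f"{case_id}{sfx}")).dataobj,
                            dtype=np.float32)
            for seq, sfx in _SUFFIX.items()
        }
        mask = np.asarray(nib.load(str(cohort_dir / f"{case_id}_mask.nii.gz")).dataobj,
                          dtype=np.uint8)
        studies.append(MriStudy(sequences=sequences, mask=mask, case_id=case_id))
    return studies, frame


def cohort_hash(cohort_dir) -> str:
    """SHA-256 over the cohort CSV and manifest (order-stable)."""
    h = hashlib.sha256()
    for name in ("cohort.csv", "manifest.json"):
        h.update((Path(cohort_dir) / name).read_bytes())
    return h.hexdigest()
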