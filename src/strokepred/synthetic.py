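"""Synthetic study generator for disconnection-based outcome prediction.

Real studies of this kind start from patients' lesion masks, derive voxelwise
white-matter disconnection probability maps from normative tractography,
summarise them over a grey-matter parcellation (here 372 structures), and
express each patient as a mixture over a low-dimensional disconnection basis
(here 46 components).  Motor ability is measured with a battery of
lateralized clinical tests at three time points (2 weeks, 3 months, 1 year)
and reduced to one latent factor per body side.

This module generates complete synthetic studies with that statistical
structure and a fully recorded ground truth, so that every downstream stage
(region averaging, component-score estimation, behavioral PCA, the six
regression families and their evaluation protocol) can be tested for
parameter recovery without any external data.

Every generator is a pure function of its parameters and a master seed;
sub-generators derive child seeds by the fixed offsets in
:data:`strokepred._utils.SEED_OFFSETS`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._utils import child_seed

TIMEPOINTS = ("2w", "3m", "1y")
SIDES = ("left", "right")

#: Battery tests per body side: (name, location, scale of a typical cohort).
#: Higher value always means better performance (the nine-hole peg test is
#: expressed as pegs per second, not completion time).
BATTERY_TESTS = (
    ("shoulder_flexion_deg", 120.0, 40.0),
    ("wrist_extension_deg", 45.0, 20.0),
    ("grip_kg", 22.0, 10.0),
    ("nine_hpt_pegs_per_s", 0.45, 0.18),
    ("arat_total", 38.0, 15.0),
    ("walking_index", 3.5, 1.5),
    ("motricity_index", 70.0, 25.0),
    ("ankle_dorsiflexion_deg", 15.0, 8.0),
)

DEFAULT_N_REGIONS = 372
DEFAULT_N_COMPONENTS = 46
DEFAULT_N_PATIENTS = 62


class DimensionError(ValueError):
    """Requested dimensions are inconsistent (e.g. more components than regions)."""


class CapacityError(ValueError):
    """A voxel grid is too small to host the requested parcellation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ComponentBasis:
    """A regions x components loading matrix defining the disconnection space."""

    loadings: np.ndarray
    region_labels: list[str]
    component_ids: list[str]

    def __post_init__(self):
        self.loadings = np.asarray(self.loadings, dtype=float)
        n_regions, n_components = self.loadings.shape
        if len(self.region_labels) != n_regions:
            raise DimensionError("region_labels length does not match loadings rows")
        if len(self.component_ids) != n_components:
            raise DimensionError("component_ids length does not match loadings columns")
        if n_components > n_regions:
            raise DimensionError(
                f"n_components ({n_components}) exceeds n_regions ({n_regions})"
            )
        sv = np.linalg.svd(self.loadings, compute_uv=False)
        if sv[-1] <= 1e-8 * sv[0]:
            raise DimensionError("basis columns are not linearly independent")

    @property
    def n_regions(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.loadings, index=self.region_labels, columns=self.component_ids
        )
        df.index.name = "region_label"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "ComponentBasis":
        df = pd.read_csv(path, index_col="region_label")
        return cls(df.to_numpy(float), list(df.index), list(df.columns))


@dataclass
class DisconnectionDataset:
    """Patients x regions table of average disconnection probabilities in [0, 1]."""

    values: np.ndarray
    patient_ids: list[str]
    region_labels: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (patients x regions)")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("disconnection values contain missing entries")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("disconnection values must lie in [0, 1]")
        if len(self.patient_ids) != self.values.shape[0]:
            raise ValueError("patient_ids length mismatch")
        if len(self.region_labels) != self.values.shape[1]:
            raise ValueError("region_labels length mismatch")

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(
            self.values, index=self.patient_ids, columns=self.region_labels
        )
        df.index.name = "patient_id"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DisconnectionDataset":
        df = pd.read_csv(path, index_col="patient_id")
        return cls(df.to_numpy(float), list(df.index.astype(str)), list(df.columns))


@dataclass
class SyntheticTruth:
    """Ground-truth parameters of a generated study.

    mixing_weights are recorded on the post-squash scale (the affine map that
    carries the raw component mixture into [0, 1] rescales every weight by the
    same factor), so with zero noise and no clipping the per-patient
    regression of the disconnection vector on the basis recovers them exactly.
    """

    mixing_weights: np.ndarray  # n_patients x n_components, post-squash scale
    outcome_weights: np.ndarray  # 2 sides x 3 timepoints x n_components (effective)
    outcome_noise_sd: np.ndarray  # 2 x 3, in units of the signal SD
    disconnection_noise_sd: float
    latent_factor_corr: float
    squash_intercept: float = 0.5
    squash_scale: float = 0.0
    latent_factors: np.ndarray | None = None  # n_patients x 2 x 3, realized
    latent_signals: np.ndarray | None = None  # noiseless part of the above

    def __post_init__(self):
        self.mixing_weights = np.asarray(self.mixing_weights, dtype=float)
        self.outcome_weights = np.asarray(self.outcome_weights, dtype=float)
        self.outcome_noise_sd = np.asarray(self.outcome_noise_sd, dtype=float)
        if np.any(self.outcome_noise_sd < 0) or self.disconnection_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not abs(self.latent_factor_corr) < 1:
            raise ValueError("|latent_factor_corr| must be < 1")

    @property
    def generating_r2(self) -> np.ndarray:
        """Per side x timepoint fraction of latent variance that is signal."""
        return 1.0 / (1.0 + self.outcome_noise_sd**2)

    def dominant_components(self, side: int, timepoint: int, k: int = 3) -> list[int]:
        w = np.abs(self.outcome_weights[side, timepoint])
        return list(np.argsort(w)[::-1][:k])

    def to_json(self, path) -> None:
        d = {
            "mixing_weights": self.mixing_weights.tolist(),
            "outcome_weights": self.outcome_weights.tolist(),
            "outcome_noise_sd": self.outcome_noise_sd.tolist(),
            "disconnection_noise_sd": self.disconnection_noise_sd,
            "latent_factor_corr": self.latent_factor_corr,
            "squash_intercept": self.squash_intercept,
            "squash_scale": self.squash_scale,
            "latent_factors": None
            if self.latent_factors is None
            else self.latent_factors.tolist(),
            "latent_signals": None
            if self.latent_signals is None
            else self.latent_signals.tolist(),
        }
        Path(path).write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            mixing_weights=np.asarray(d["mixing_weights"]),
            outcome_weights=np.asarray(d["outcome_weights"]),
            outcome_noise_sd=np.asarray(d["outcome_noise_sd"]),
            disconnection_noise_sd=d["disconnection_noise_sd"],
            latent_factor_corr=d["latent_factor_corr"],
            squash_intercept=d["squash_intercept"],
            squash_scale=d["squash_scale"],
            latent_factors=None
            if d["latent_factors"] is None
            else np.asarray(d["latent_factors"]),
            latent_signals=None
            if d["latent_signals"] is None
            else np.asarray(d["latent_signals"]),
        )


@dataclass
class MotorBattery:
    """Raw motor test scores, one row per patient x timepoint.

    Columns are ``l_<test>`` / ``r_<test>`` for the eight tests per side.
    """

    data: pd.DataFrame

    def __post_init__(self):
        required = {"patient_id", "timepoint"} | set(self.test_columns())
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"battery table missing columns: {sorted(missing)}")
        bad_tp = set(self.data["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise ValueError(f"unknown timepoint labels: {sorted(bad_tp)}")
        for col in ("l_arat_total", "r_arat_total"):
            v = self.data[col]
            if v.min() < 0 or v.max() > 57:
                raise ValueError(f"{col} outside [0, 57]")
        vals = self.data[self.test_columns()].to_numpy(float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("battery contains non-finite scores")

    @staticmethod
    def test_columns() -> list[str]:
        return [f"{p}_{name}" for p in ("l", "r") for name, _, _ in BATTERY_TESTS]

    def matrix(self, timepoint: str) -> tuple[np.ndarray, list[str], list[str]]:
        """Return (patients x tests matrix, patient ids, test names) at a timepoint."""
        sub = self.data[self.data["timepoint"] == timepoint].sort_index()
        cols = self.test_columns()
        return sub[cols].to_numpy(float), list(sub["patient_id"].astype(str)), cols

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "MotorBattery":
        return cls(pd.read_csv(path))


@dataclass
class LabeledVolume:
    """A 3-D integer label volume (0 = background) with voxel geometry."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("volume must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("labeled volume must be integer-typed")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.affine is None:
            self.affine = np.diag(list(self.voxel_size) + [1.0])
        self.affine = np.asarray(self.affine, dtype=float)

    def to_nifti(self, path) -> None:
        import nibabel as nib

        img = nib.Nifti1Image(self.data.astype(np.int32), self.affine)
        img.header.set_data_dtype(np.int32)
        nib.save(img, str(path))

    @classmethod
    def from_nifti(cls, path) -> "LabeledVolume":
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asanyarray(img.dataobj).astype(np.int32)
        vx = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(data=data, voxel_size=vx, affine=np.asarray(img.affine))


def save_probability_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    """Write a float64 probability volume as NIfTI-1 (bit-exact round trip)."""
    import nibabel as nib

    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def load_probability_volume(path) -> tuple[np.ndarray, np.ndarray]:
    import nibabel as nib

    img = nib.load(str(path))
    return np.asanyarray(img.dataobj).astype(np.float64), np.asarray(img.affine)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------


def generate_component_basis(
    n_regions: int = DEFAULT_N_REGIONS,
    n_components: int = DEFAULT_N_COMPONENTS,
    smoothness: float = 0.5,
    seed: int = 0,
    orthonormalize: bool = False,
) -> ComponentBasis:
    """Generate a random spatially smooth component basis.

    Loadings start as i.i.d. standard normals and are smoothed along the
    region ordering with a moving average whose half-width grows with
    ``smoothness`` (the region index stands in for spatial adjacency), so
    adjacent-region autocorrelation increases with ``smoothness``.  With
    ``orthonormalize`` the columns are replaced by their QR orthonormal
    factor, giving condition number 1.
    """
    if n_components < 1 or n_regions < n_components:
        raise DimensionError(
            f"need n_regions >= n_components >= 1, got {n_regions}, {n_components}"
        )
    if smoothness < 0:
        raise ValueError("smoothness must be >= 0")
    rng = np.random.default_rng(child_seed(seed, "basis"))
    raw = rng.normal(size=(n_regions, n_components))
    half = int(round(5 * smoothness))
    if half > 0:
        kernel = np.ones(2 * half + 1) / (2 * half + 1)
        sm = np.empty_like(raw)
        for j in range(n_components):
            padded = np.pad(raw[:, j], half, mode="edge")
            sm[:, j] = np.convolve(padded, kernel, mode="valid")
        raw = sm
        # restore unit column scale so smoothness does not shrink loadings
        raw /= raw.std(axis=0, ddof=0)
    if orthonormalize:
        q, _ = np.linalg.qr(raw)
        raw = q
    labels = [f"region_{i + 1:03d}" for i in range(n_regions)]
    comp_ids = [f"C{j + 1}" for j in range(n_components)]
    return ComponentBasis(raw, labels, comp_ids)


def _sparse_weights(
    rng: np.random.Generator, n_components: int, n_active: int
) -> np.ndarray:
    """Sparse weight vector: sign x |Normal| magnitudes at a random support,
    sorted in decreasing magnitude so the dominant components are unambiguous."""
    support = rng.choice(n_components, size=n_active, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_active)
    mags = np.sort(np.abs(rng.normal(size=n_active)))[::-1]
    w = np.zeros(n_components)
    w[support] = signs * mags
    return w


def generate_disconnections(
    basis: ComponentBasis,
    n_patients: int = DEFAULT_N_PATIENTS,
    n_active: int = 5,
    noise_sd: float = 0.02,
    seed: int = 0,
    *,
    k_active: int = 5,
    outcome_noise_sd: float = 0.5,
    latent_factor_corr: float = 0.5,
    squash: str = "affine",
) -> tuple[DisconnectionDataset, SyntheticTruth]:
    """Generate patient disconnection maps as sparse mixtures over the basis.

    Each patient mixes ``n_active`` components with signed, magnitude-ordered
    weights; the noiseless mixture is squashed into [0, 1] and Gaussian noise
    of SD ``noise_sd`` is added before clipping.  The default squash is the
    affine map of the mixture range onto [0.02, 0.98], which keeps region
    vectors exactly linear in the (rescaled) weights; ``squash="logistic"``
    applies instead a scaled logistic centered at the mixture median, which
    bounds values smoothly but is not linearity-preserving.

    Returns the dataset and a :class:`SyntheticTruth` carrying the
    post-squash mixing weights plus the outcome-model parameters
    (``k_active`` nonzero outcome weights per side x timepoint,
    ``outcome_noise_sd`` in units of the latent signal SD, and the left/right
    latent correlation) consumed by :func:`generate_motor_battery`.
    """
    if not (1 <= n_active <= basis.n_components):
        raise ValueError("need 1 <= n_active <= n_components")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng_w = np.random.default_rng(child_seed(seed, "mixing_weights"))
    rng_n = np.random.default_rng(child_seed(seed, "disconnection_noise"))
    rng_o = np.random.default_rng(child_seed(seed, "outcome_weights"))

    W = np.vstack(
        [_sparse_weights(rng_w, basis.n_components, n_active) for _ in range(n_patients)]
    )
    raw = W @ basis.loadings.T  # n_patients x n_regions
    lo, hi = raw.min(), raw.max()
    margin = 0.02
    if hi > lo:
        if squash == "affine":
            c1 = (1 - 2 * margin) / (hi - lo)
            c0 = margin - lo * c1
            squashed = c0 + c1 * raw
            W_eff = W * c1
        elif squash == "logistic":
            center = np.median(raw)
            scale = (hi - lo) / 8.0
            squashed = 1.0 / (1.0 + np.exp(-(raw - center) / scale))
            c0, c1 = float(center), float(scale)
            W_eff = W  # logistic squash has no exact linear-scale counterpart
        else:
            raise ValueError(f"unknown squash {squash!r}")
    else:  # degenerate all-zero mixture: squash of zero is the constant 0.5
        c0, c1 = 0.5, 0.0
        squashed = np.full_like(raw, 0.5)
        W_eff = W * 0.0
    values = squashed + rng_n.normal(0.0, noise_sd, size=raw.shape)
    values = np.clip(values, 0.0, 1.0)

    # outcome model: disjoint left/right supports per timepoint so the
    # requested latent correlation can be imposed exactly by mixing
    n_sides, n_tp = len(SIDES), len(TIMEPOINTS)
    # disjoint left/right supports need 2*k_active components; clamp for
    # small bases so the default works at any dimensionality
    k_active = max(1, min(k_active, basis.n_components // 2))
    outcome_weights = np.zeros((n_sides, n_tp, basis.n_components))
    for t in range(n_tp):
        idx = rng_o.choice(basis.n_components, size=2 * k_active, replace=False)
        for s, block in enumerate((idx[:k_active], idx[k_active:])):
            signs = rng_o.choice([-1.0, 1.0], size=k_active)
            mags = np.sort(np.abs(rng_o.normal(size=k_active)))[::-1]
            outcome_weights[s, t, block] = signs * mags

    patient_ids = [f"P{i + 1:03d}" for i in range(n_patients)]
    ds = DisconnectionDataset(values, patient_ids, list(basis.region_labels))
    truth = SyntheticTruth(
        mixing_weights=W_eff,
        outcome_weights=outcome_weights,
        outcome_noise_sd=np.full((n_sides, n_tp), float(outcome_noise_sd)),
        disconnection_noise_sd=float(noise_sd),
        latent_factor_corr=float(latent_factor_corr),
        squash_intercept=c0,
        squash_scale=c1,
    )
    return ds, truth


def _standardize_vec(v: np.ndarray) -> tuple[np.ndarray, float, float]:
    m, s = float(v.mean()), float(v.std(ddof=0))
    if s == 0:
        return v - m, m, 1.0
    return (v - m) / s, m, s


def generate_motor_battery(
    truth: SyntheticTruth,
    component_scores: np.ndarray,
    seed: int = 0,
    test_noise_sd: float = 0.2,
) -> MotorBattery:
    """Generate the raw motor battery from latent left/right factors.

    For each timepoint a raw factor per side is built as
    ``outcome_weights . scores + noise`` (noise SD = ``outcome_noise_sd`` x
    the empirical signal SD, so the generating signal fraction of latent
    variance is ``1 / (1 + outcome_noise_sd**2)``); both raw factors are
    standardized and the right factor is replaced by the
    ``latent_factor_corr``-mix of the two, which imposes exactly the
    requested left/right correlation because the two sides' weight supports
    are disjoint.  Each raw test score is a monotone affine map of its side's
    latent factor plus test-specific noise (``test_noise_sd`` in latent-SD
    units); the ARAT total is rounded and clamped to [0, 57].

    The realized latent factors and their noiseless signal parts are stored
    on ``truth`` (``latent_factors``, ``latent_signals``), and
    ``truth.outcome_weights`` is updated to the effective (standardized,
    mixed) weights actually linking component scores to the latents.
    """
    scores = np.asarray(component_scores, dtype=float)
    n_patients = scores.shape[0]
    if scores.shape[1] != truth.outcome_weights.shape[2]:
        raise ValueError("component_scores width does not match outcome_weights")
    rng_l = np.random.default_rng(child_seed(seed, "latent_noise"))
    rng_b = np.random.default_rng(child_seed(seed, "battery_noise"))
    rho = truth.latent_factor_corr

    n_tp = len(TIMEPOINTS)
    latents = np.zeros((n_patients, 2, n_tp))
    signals = np.zeros((n_patients, 2, n_tp))
    eff_weights = np.zeros_like(truth.outcome_weights)
    for t in range(n_tp):
        raw = {}
        sig = {}
        w_std = {}
        for s in range(2):
            w = truth.outcome_weights[s, t]
            signal = scores @ w
            sig_sd = signal.std(ddof=0)
            if sig_sd == 0:
                sig_sd = 1.0
            # noise is demeaned, projected orthogonal to the signal and scaled
            # exactly, so the generating signal fraction of latent variance is
            # exactly 1 / (1 + outcome_noise_sd**2) rather than only expected
            noise = rng_l.normal(0.0, 1.0, n_patients)
            noise -= noise.mean()
            sig_c = signal - signal.mean()
            if sig_c @ sig_c > 0:
                noise -= (noise @ sig_c) / (sig_c @ sig_c) * sig_c
            nsd = noise.std(ddof=0)
            target = truth.outcome_noise_sd[s, t] * sig_sd
            noise *= (target / nsd) if nsd > 0 else 0.0
            z, m, sd = _standardize_vec(signal + noise)
            raw[s] = z
            sig[s] = (signal - signal.mean()) / sd
            w_std[s] = w / sd
        latents[:, 0, t] = raw[0]
        signals[:, 0, t] = sig[0]
        eff_weights[0, t] = w_std[0]
        mix = np.sqrt(1.0 - rho**2)
        latents[:, 1, t] = rho * raw[0] + mix * raw[1]
        signals[:, 1, t] = rho * sig[0] + mix * sig[1]
        eff_weights[1, t] = rho * w_std[0] + mix * w_std[1]

    truth.latent_factors = latents
    truth.latent_signals = signals
    truth.outcome_weights = eff_weights

    rows = []
    for t, tp in enumerate(TIMEPOINTS):
        for i in range(n_patients):
            row = {"patient_id": f"P{i + 1:03d}", "timepoint": tp}
            for s, prefix in enumerate(("l", "r")):
                latent = latents[i, s, t]
                for name, loc, scale in BATTERY_TESTS:
                    noisy = latent + rng_b.normal(0.0, test_noise_sd)
                    val = loc + scale * noisy
                    if name == "arat_total":
                        val = float(np.clip(round(val), 0, 57))
                    row[f"{prefix}_{name}"] = val
            rows.append(row)
    return MotorBattery(pd.DataFrame(rows))


def generate_voxel_study(
    basis: ComponentBasis,
    dataset: DisconnectionDataset,
    grid_shape: tuple[int, int, int] = (48, 48, 48),
    seed: int = 0,
    tract_n_parcels: int = 8,
) -> tuple[LabeledVolume, list[np.ndarray], LabeledVolume]:
    """Expand a region-level dataset into voxel volumes.

    The grid is partitioned into ``n_regions`` contiguous equal-size parcels
    (flat voxel order; remaining voxels are background 0).  Each patient's
    probability volume fills parcel *r* with the patient's region-*r* value,
    so region averaging inverts the construction exactly.  The tract mask
    marks the voxels of ``tract_n_parcels`` randomly chosen parcels, a toy
    stand-in for a white-matter tract such as the corticospinal tract.
    """
    n_regions = basis.n_regions
    total = int(np.prod(grid_shape))
    vox_per = total // n_regions
    if vox_per < 1:
        raise CapacityError(
            f"grid {grid_shape} has {total} voxels; cannot host {n_regions} parcels"
        )
    labels_flat = np.zeros(total, dtype=np.int32)
    for r in range(n_regions):
        labels_flat[r * vox_per : (r + 1) * vox_per] = r + 1
    atlas = LabeledVolume(labels_flat.reshape(grid_shape))

    volumes = []
    for p in range(dataset.n_patients):
        vol = np.zeros(total, dtype=np.float64)
        for r in range(n_regions):
            vol[r * vox_per : (r + 1) * vox_per] = dataset.values[p, r]
        volumes.append(vol.reshape(grid_shape))

    rng = np.random.default_rng(child_seed(seed, "voxel"))
    tract_parcels = rng.choice(n_regions, size=min(tract_n_parcels, n_regions), replace=False)
    tract_flat = np.zeros(total, dtype=np.int32)
    for r in tract_parcels:
        tract_flat[r * vox_per : (r + 1) * vox_per] = 1
    tract = LabeledVolume(tract_flat.reshape(grid_shape))
    return atlas, volumes, tract
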