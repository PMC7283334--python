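"""Digital brain phantom and synthetic subject cohorts.

The phantom is a deterministic geometric stand-in for a FreeSurfer-style
segmentation: a cerebral ellipsoid with a cortical grey-matter ribbon split
into Desikan-Killiany-named angular parcels, subcortical nuclei, cerebellar
lobes with a GM shell and WM core, a pons and midbrain on the midline, lateral
ventricles (CSF), a deep cerebral white-matter core, and two internal-carotid
tubes below the brain for image-derived input-function extraction.

The 84-entry candidate-region table (68 cortical parcels, 10 subcortical
nuclei, 4 cerebellar regions, pons and midbrain) is the set of possible
intensity-normalization regions the pipeline ranks.

Cohorts carry planted, region-specific linear age effects on tracer uptake and
on volume.  The default effect specification sets both pons slopes to exactly
zero: the pons is the planted "ideal reference region" the downstream ranking
is expected to recover.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LabelAtlas",
    "TissueMaps",
    "AtlasSpec",
    "CohortTruth",
    "PhantomSizingError",
    "CEREBRAL_WM_ID",
    "CSF_ID",
    "CAROTID_ID",
    "candidate_region_table",
    "build_phantom",
    "default_effect_spec",
    "clinical_effect_spec",
    "baseline_kinetics",
    "sample_cohort",
    "sample_clinical_cohort",
]

# Desikan-Killiany cortical parcel base names (34 per hemisphere).
DK_PARCELS = [
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "frontalpole", "fusiform", "inferiorparietal",
    "inferiortemporal", "insula", "isthmuscingulate", "lateraloccipital",
    "lateralorbitofrontal", "lingual", "medialorbitofrontal", "middletemporal",
    "paracentral", "parahippocampal", "parsopercularis", "parsorbitalis",
    "parstriangularis", "pericalcarine", "postcentral", "posteriorcingulate",
    "precentral", "precuneus", "rostralanteriorcingulate",
    "rostralmiddlefrontal", "superiorfrontal", "superiorparietal",
    "superiortemporal", "supramarginal", "temporalpole", "transversetemporal",
]

SUBCORTICAL = ["thalamus", "caudate", "putamen", "pallidum", "hippocampus"]

# Non-candidate labels (spill compartments and blood pool).
CEREBRAL_WM_ID = 90
CSF_ID = 91
CAROTID_ID = 92

_SPECIAL_ROWS = [
    (CEREBRAL_WM_ID, "cerebral-white-matter", "midline", "WM"),
    (CSF_ID, "lateral-ventricles", "midline", "CSF"),
    (CAROTID_ID, "internal-carotid", "midline", "blood"),
]

# Azimuthal split counts per polar band; sums to 34 parcels per hemisphere.
_PARCEL_BANDS = [4, 6, 7, 7, 6, 4]


class PhantomSizingError(ValueError):
    """Raised when a requested region cannot be placed on the grid."""


def candidate_region_table() -> pd.DataFrame:
    """The 84-entry table of candidate normalization regions.

    Columns: region_id, name (unique), base (shared by left/right pairs),
    hemisphere in {left, right, midline}, tissue_class in {GM, WM, mixed},
    candidate (bool).
    """
    rows = []
    rid = 1
    for base in DK_PARCELS:
        for hemi in ("left", "right"):
            rows.append((rid, f"{hemi}_{base}", base, hemi, "GM", True))
            rid += 1
    for base in SUBCORTICAL:
        for hemi in ("left", "right"):
            rows.append((rid, f"{hemi}_{base}", base, hemi, "GM", True))
            rid += 1
    for base, cls in (("cerebellum-cortex", "GM"), ("cerebellum-white-matter", "WM")):
        for hemi in ("left", "right"):
            rows.append((rid, f"{hemi}_{base}", base, hemi, cls, True))
            rid += 1
    rows.append((rid, "pons", "pons", "midline", "mixed", True))
    rid += 1
    rows.append((rid, "midbrain", "midbrain", "midline", "mixed", True))
    df = pd.DataFrame(
        rows, columns=["region_id", "name", "base", "hemisphere", "tissue_class", "candidate"]
    )
    assert len(df) == 84
    return df


def full_region_table() -> pd.DataFrame:
    """Candidate table plus the non-candidate spill/blood labels."""
    cand = candidate_region_table()
    extra = pd.DataFrame(
        [(i, n, n, h, c, False) for i, n, h, c in _SPECIAL_ROWS],
        columns=cand.columns,
    )
    return pd.concat([cand, extra], ignore_index=True)


@dataclass(frozen=True)
class AtlasSpec:
    """Geometric parameters of the phantom, in fractions of the grid extent
    (mm values where noted).  The defaults place every mandatory region."""

    cerebrum_center: tuple = (0.0, 0.02, 0.12)
    cerebrum_axes: tuple = (0.30, 0.36, 0.26)
    ribbon_mm: float = 4.0           # cortical GM shell thickness
    ventricle_offset: tuple = (0.06, 0.0, 0.10)
    ventricle_axes: tuple = (0.035, 0.10, 0.05)
    cerebellum_center: tuple = (0.10, -0.28, -0.14)
    cerebellum_axes: tuple = (0.085, 0.09, 0.08)
    pons_center_xy: tuple = (0.0, -0.08)
    pons_radius: float = 0.045
    pons_z: tuple = (-0.26, -0.16)
    midbrain_radius: float = 0.035
    midbrain_z: tuple = (-0.16, -0.11)
    carotid_offset_x: float = 0.05
    carotid_y: float = 0.02
    carotid_radius_mm: float = 2.0   # 4 mm diameter tubes
    carotid_z: tuple = (-0.45, -0.32)
    subcortical: dict = field(default_factory=lambda: {
        "thalamus": ((0.07, -0.04, 0.04), (0.040, 0.050, 0.040)),
        "caudate": ((0.09, 0.08, 0.08), (0.030, 0.060, 0.030)),
        "putamen": ((0.14, 0.04, 0.04), (0.035, 0.055, 0.040)),
        "pallidum": ((0.12, 0.00, 0.02), (0.025, 0.035, 0.025)),
        "hippocampus": ((0.13, -0.10, -0.02), (0.030, 0.055, 0.025)),
    })


@dataclass
class LabelAtlas:
    """Integer label volume plus its region table."""

    labels: np.ndarray                # 3D int16
    voxel_size_mm: float
    region_table: pd.DataFrame        # full table (candidates + specials)

    @property
    def candidates(self) -> pd.DataFrame:
        return self.region_table[self.region_table["candidate"]].reset_index(drop=True)

    def region_mask(self, region_id: int) -> np.ndarray:
        return self.labels == region_id

    def region_volumes_mm3(self) -> pd.Series:
        counts = np.bincount(self.labels.ravel(), minlength=int(self.labels.max()) + 1)
        vv = self.voxel_size_mm ** 3
        cand = self.candidates
        return pd.Series(
            counts[cand["region_id"].to_numpy()] * vv,
            index=cand["name"], name="volume_mm3",
        )


@dataclass
class TissueMaps:
    """Tissue fraction maps on the atlas grid.

    ``gm`` is the target (parenchyma) compartment of the partial-volume
    correction and covers all candidate regions, including brainstem and
    cerebellar white matter; ``wm`` is the deep cerebral white-matter core,
    ``csf`` the ventricles.  gm+wm+csf <= 1 voxelwise.
    """

    gm: np.ndarray
    wm: np.ndarray
    csf: np.ndarray

    def __post_init__(self):
        total = self.gm + self.wm + self.csf
        if (self.gm < 0).any() or (self.wm < 0).any() or (self.csf < 0).any():
            raise ValueError("tissue fractions must be nonnegative")
        if (total > 1 + 1e-9).any():
            raise ValueError("tissue fractions must sum to <= 1 voxelwise")


def _coords(grid_shape, voxel_size_mm):
    """Normalized coordinates in fractions of the z-extent, centered so that
    the x axis mirrors exactly under np.flip (center at (n-1)/2)."""
    extent = grid_shape[2] * voxel_size_mm
    axes = [
        (np.arange(n) - (n - 1) / 2.0) * voxel_size_mm / extent
        for n in grid_shape
    ]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    return x, y, z, extent


def _ellipsoid(x, y, z, center, axes_):
    if min(axes_) <= 0:
        raise PhantomSizingError(f"ellipsoid with nonpositive axis {axes_}")
    return ((x - center[0]) / axes_[0]) ** 2 + ((y - center[1]) / axes_[1]) ** 2 + (
        (z - center[2]) / axes_[2]
    ) ** 2 <= 1.0


def build_phantom(grid_shape=(96, 96, 96), voxel_size_mm=2.0, atlas_spec=None):
    """Build the deterministic label atlas and tissue maps.

    Structures are painted in priority order into empty voxels only, so the
    result is independent of floating-point traversal order and exactly
    mirror-symmetric in x (left/right labels swap under an x-flip).

    Raises
    ------
    PhantomSizingError
        if any mandatory region ends up empty (grid too small or a degenerate
        atlas_spec), naming the offending region.
    """
    spec = atlas_spec or AtlasSpec()
    table = full_region_table()
    name_to_id = dict(zip(table["name"], table["region_id"]))
    x, y, z, extent = _coords(grid_shape, voxel_size_mm)
    labels = np.zeros(grid_shape, dtype=np.int16)

    def paint(mask, rid):
        labels[(labels == 0) & mask] = rid

    cc, ca = np.array(spec.cerebrum_center), np.array(spec.cerebrum_axes)
    t = spec.ribbon_mm / extent
    inner_axes = ca - t
    if (inner_axes <= 0).any():
        raise PhantomSizingError("cerebrum ribbon thicker than cerebrum axes")
    outer = _ellipsoid(x, y, z, cc, ca)
    inner = _ellipsoid(x, y, z, cc, inner_axes)

    # 1. ventricles (CSF)
    vo = np.array(spec.ventricle_offset)
    for sx in (+1, -1):
        c = cc + vo * [sx, 1, 1]
        paint(_ellipsoid(x, y, z, c, spec.ventricle_axes) & inner, CSF_ID)

    # 2. subcortical nuclei
    for base, (off, axes_) in spec.subcortical.items():
        for hemi, sx in (("left", -1), ("right", +1)):
            c = cc + np.array(off) * [sx, 1, 1]
            m = _ellipsoid(x, y, z, c, axes_) & inner
            paint(m, name_to_id[f"{hemi}_{base}"])

    # 3. cortical ribbon, split into angular parcels per hemisphere
    shell = outer & ~inner
    wx = (x - cc[0]) / ca[0]
    wy = (y - cc[1]) / ca[1]
    wz = (z - cc[2]) / ca[2]
    wn = np.sqrt(wx**2 + wy**2 + wz**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(wz / np.where(wn > 0, wn, 1.0), -1, 1))
    phi = np.arctan2(wy, np.abs(wx))  # folded azimuth in [-pi/2, pi/2]
    nband = len(_PARCEL_BANDS)
    iband = np.minimum((theta / np.pi * nband).astype(int), nband - 1)
    offsets = np.cumsum([0] + _PARCEL_BANDS[:-1])
    nphi = np.asarray(_PARCEL_BANDS)[iband]
    iphi = np.minimum(((phi + np.pi / 2) / np.pi * nphi).astype(int), nphi - 1)
    parcel = offsets[iband] + iphi   # 0..33
    for ip, base in enumerate(DK_PARCELS):
        for hemi, sel in (("left", wx < 0), ("right", wx >= 0)):
            paint(shell & sel & (parcel == ip), name_to_id[f"{hemi}_{base}"])

    # 4. deep cerebral white matter (remainder of the interior)
    paint(inner, CEREBRAL_WM_ID)

    # 5. pons and midbrain (midline cylinders)
    px, py = spec.pons_center_xy
    if spec.pons_radius <= 0:
        raise PhantomSizingError("pons radius must be positive")
    rad2 = (x - px) ** 2 + (y - py) ** 2
    paint((rad2 <= spec.pons_radius**2) & (z >= spec.pons_z[0]) & (z <= spec.pons_z[1]),
          name_to_id["pons"])
    paint((rad2 <= spec.midbrain_radius**2) & (z >= spec.midbrain_z[0]) & (z <= spec.midbrain_z[1]),
          name_to_id["midbrain"])

    # 6. cerebellum: GM shell around WM core, two mirrored lobes
    ce_c, ce_a = np.array(spec.cerebellum_center), np.array(spec.cerebellum_axes)
    core_axes = ce_a - t
    if (core_axes <= 0).any():
        raise PhantomSizingError("cerebellum smaller than its GM shell thickness")
    for hemi, sx in (("left", -1), ("right", +1)):
        c = ce_c * [sx, 1, 1]
        lobe = _ellipsoid(x, y, z, c, ce_a)
        core = _ellipsoid(x, y, z, c, core_axes)
        paint(lobe & ~core, name_to_id[f"{hemi}_cerebellum-cortex"])
        paint(core, name_to_id[f"{hemi}_cerebellum-white-matter"])

    # 7. carotid tubes
    rmm = spec.carotid_radius_mm / extent
    for sx in (+1, -1):
        m = ((x - sx * spec.carotid_offset_x) ** 2 + (y - spec.carotid_y) ** 2 <= rmm**2) & (
            z >= spec.carotid_z[0]
        ) & (z <= spec.carotid_z[1])
        paint(m, CAROTID_ID)

    present = set(np.unique(labels)) - {0}
    for _, row in table.iterrows():
        if row["region_id"] not in present:
            raise PhantomSizingError(
                f"region '{row['name']}' is empty on grid {grid_shape}; "
                "increase the grid or adjust the atlas spec"
            )

    cand_ids = table.loc[table["candidate"], "region_id"].to_numpy()
    gm = np.isin(labels, cand_ids).astype(np.float64)
    wm = (labels == CEREBRAL_WM_ID).astype(np.float64)
    csf = (labels == CSF_ID).astype(np.float64)
    atlas = LabelAtlas(labels=labels, voxel_size_mm=float(voxel_size_mm), region_table=table)
    return atlas, TissueMaps(gm=gm, wm=wm, csf=csf)


# ---------------------------------------------------------------------------
# Kinetic ground truth and effect specifications
# ---------------------------------------------------------------------------

#: reference age (years) about which fractional age slopes are expressed
REFERENCE_AGE = 25.0
#: plasma glucose (mmol/L) at which baseline K1 values are expressed
REFERENCE_GLUCOSE = 5.0
#: probability that a sampled subject is female
P_FEMALE = 0.55

_SPEC_SEED = 20260928  # fixes the default per-region slope/kinetics draws


def baseline_kinetics(region_table=None) -> pd.DataFrame:
    """Baseline irreversible two-tissue-compartment parameters per label.

    Cortical/subcortical grey matter around K1=0.10, k2=0.15, k3=0.05 /min
    (net Ki ~ 0.025 /min); white-matter-like tissue (cerebellar WM, pons,
    midbrain, deep WM) at roughly half the grey-matter uptake.  Values vary
    deterministically by +-10% across regions.  CSF has zero uptake; the
    carotid label is pure blood (vB = 1).
    """
    table = region_table if region_table is not None else full_region_table()
    rng = np.random.default_rng(_SPEC_SEED)
    rows = []
    for _, r in table.iterrows():
        u = rng.uniform(0.9, 1.1, size=3)
        cls = r["tissue_class"]
        if cls == "CSF":
            k1, k2, k3, vb = 0.0, 1e-3, 1e-3, 0.0
        elif cls == "blood":
            k1, k2, k3, vb = 0.0, 1e-3, 1e-3, 1.0
        elif cls == "GM":
            k1, k2, k3, vb = 0.10 * u[0], 0.15 * u[1], 0.050 * u[2], 0.04
            if r["base"] == "putamen":
                k1 *= 1.2
        else:  # WM / mixed (brainstem)
            k1, k2, k3, vb = 0.050 * u[0], 0.12 * u[1], 0.025 * u[2], 0.03
        rows.append((r["region_id"], r["name"], k1, k2, k3, vb))
    df = pd.DataFrame(rows, columns=["region_id", "name", "K1", "k2", "k3", "vB"])
    return df.set_index("name")


def _base_spec_frame(table):
    rng = np.random.default_rng(_SPEC_SEED + 1)
    bases = list(dict.fromkeys(table["base"]))
    slope_u = {b: -rng.uniform(0.001, 0.004) for b in bases}
    slope_v = {b: -rng.uniform(0.001, 0.004) for b in bases}
    # the planted null: the pons is age-invariant in uptake and volume
    slope_u["pons"] = 0.0
    slope_v["pons"] = 0.0
    slope_u["midbrain"] = -0.0015
    slope_v["midbrain"] = -0.0012
    slope_u["lateral-ventricles"] = 0.0
    slope_v["lateral-ventricles"] = 0.0
    slope_u["internal-carotid"] = 0.0
    slope_v["internal-carotid"] = 0.0
    df = pd.DataFrame({
        "name": table["name"].to_numpy(),
        "age_slope_uptake": [slope_u[b] for b in table["base"]],
        "age_slope_volume": [slope_v[b] for b in table["base"]],
        "sex_uptake": 0.02,
        "mci_uptake": 0.0,
        "ad_uptake": 0.0,
        "noise_sd": 0.03,
    }).set_index("name")
    return df


def default_effect_spec() -> pd.DataFrame:
    """Default planted effects for the aging cohort.

    Fractional age slopes per year about age 25, drawn once (fixed seed) in
    [-0.004, -0.001] for every region except the pons, whose uptake and volume
    slopes are exactly zero.  Sex offset +2% (F); subject noise is a shared
    global lognormal factor (sigma 0.10) times independent regional lognormal
    noise (sigma 0.03).
    """
    return _base_spec_frame(full_region_table())


def clinical_effect_spec() -> pd.DataFrame:
    """Planted effects for the control/MCI/AD cohort.

    Widespread hypometabolism (MCI -7.5%, AD -15% in every region) plus a
    focal excess in the AD-susceptible targets: posterior cingulate reaches
    MCI -8.5% / AD -17% and precuneus MCI -10% / AD -22%; the pons is
    unaffected by group.  Because much of the target deficit is shared with
    the whole-brain mean, a whole-brain reference absorbs most of that signal
    (nearly all of it in the posterior cingulate), while a pons reference
    preserves it.
    """
    df = _base_spec_frame(full_region_table())
    df["mci_uptake"] = -0.075
    df["ad_uptake"] = -0.15
    pc = df.index.str.contains("posteriorcingulate")
    df.loc[pc, "mci_uptake"] = -0.085
    df.loc[pc, "ad_uptake"] = -0.17
    prec = df.index.str.contains("precuneus")
    df.loc[prec, "mci_uptake"] = -0.10
    df.loc[prec, "ad_uptake"] = -0.22
    for n in ("pons", "lateral-ventricles", "internal-carotid"):
        df.loc[n, ["mci_uptake", "ad_uptake"]] = 0.0
    return df


@dataclass
class CohortTruth:
    """Planted ground truth for a sampled cohort.

    ``uptake_mult`` and ``volume_mult`` are (n_subjects, n_labels) arrays of
    multiplicative factors applied to the baseline kinetics (K1) and to the
    phantom region volume, aligned with ``label_names``.
    """

    subjects: pd.DataFrame           # subject_id, age, sex, group, plasma_glucose
    label_names: list
    baseline: pd.DataFrame           # baseline_kinetics() frame
    uptake_mult: np.ndarray
    volume_mult: np.ndarray

    def true_ki(self) -> pd.DataFrame:
        """Planted net Patlak slope per subject/label.

        The measured tissue concentration is (1-vB)*(C1+C2) + vB*Cp, so the
        slope of its Patlak plot is (1-vB) * m * K1*k3/(k2+k3); the blood
        term contributes only to the intercept.
        """
        b = self.baseline.loc[self.label_names]
        ki0 = ((1.0 - b["vB"]) * b["K1"] * b["k3"] / (b["k2"] + b["k3"])).to_numpy()
        return pd.DataFrame(
            self.uptake_mult * ki0[None, :],
            index=self.subjects["subject_id"], columns=self.label_names,
        )


_GROUP_AGE_RANGES = {
    "young": (18.0, 30.0),
    "older": (65.0, 85.0),
    # clinical groups are age-matched over a narrower band, as in
    # case-control designs
    "control": (65.0, 75.0),
    "MCI": (65.0, 75.0),
    "AD": (65.0, 75.0),
}
_GROUP_GLUCOSE = {  # mean, sd in mmol/L
    "young": (4.8, 0.4),
    "older": (5.2, 0.5),
    "control": (5.2, 0.5),
    "MCI": (5.2, 0.5),
    "AD": (5.2, 0.5),
}


#: sd of the shared lognormal global metabolic factor per subject; regional
#: CMRg values are strongly correlated across a brain, and this shared
#: component is what ratio normalization (SUVR) exists to remove
GLOBAL_NOISE_SD = 0.10


def _sample_groups(group_sizes, effect_spec, seed, baseline=None,
                   global_noise_sd=GLOBAL_NOISE_SD):
    spec = effect_spec
    base = baseline if baseline is not None else baseline_kinetics()
    names = list(spec.index)
    seed_seq = [int(seed)] if np.isscalar(seed) else [int(s) for s in seed]
    rng = np.random.default_rng(seed_seq + [17])
    recs, um, vm = [], [], []
    i = 0
    for group, n in group_sizes:
        lo, hi = _GROUP_AGE_RANGES[group]
        gmu, gsd = _GROUP_GLUCOSE[group]
        for _ in range(int(n)):
            age = rng.uniform(lo, hi)
            sex = "F" if rng.random() < P_FEMALE else "M"
            glc = max(3.0, rng.normal(gmu, gsd))
            recs.append((f"sub-{i:03d}", age, sex, group, glc))
            su = spec["age_slope_uptake"].to_numpy()
            sv = spec["age_slope_volume"].to_numpy()
            sx = spec["sex_uptake"].to_numpy() * (sex == "F")
            grp = np.zeros(len(names))
            if group == "MCI":
                grp = spec["mci_uptake"].to_numpy()
            elif group == "AD":
                grp = spec["ad_uptake"].to_numpy()
            sd = spec["noise_sd"].to_numpy()
            g_u = np.exp(rng.normal(0.0, global_noise_sd))
            eps_u = g_u * np.exp(rng.normal(0.0, 1.0, len(names)) * sd)
            eps_v = np.exp(rng.normal(0.0, 1.0, len(names)) * sd)
            # effects are planted on CMRg (the biology); FDG competes with
            # glucose, so the tracer uptake multiplier carries a 1/C_glc
            # factor that cancels when Ki is converted back to CMRg
            mu = ((1 + su * (age - REFERENCE_AGE)) * (1 + sx) * (1 + grp)
                  * eps_u * (REFERENCE_GLUCOSE / glc))
            mv = (1 + sv * (age - REFERENCE_AGE)) * eps_v
            um.append(np.clip(mu, 0.05, None))
            vm.append(np.clip(mv, 0.05, None))
            i += 1
    subjects = pd.DataFrame(
        recs, columns=["subject_id", "age", "sex", "group", "plasma_glucose"]
    )
    return CohortTruth(
        subjects=subjects, label_names=names, baseline=base,
        uptake_mult=np.asarray(um), volume_mult=np.asarray(vm),
    )


def sample_cohort(n_young=30, n_older=29, effect_spec=None, seed=0, baseline=None,
                  global_noise_sd=GLOBAL_NOISE_SD):
    """Sample the two-age-group cohort (young 18-30 y, older 65-85 y).

    Ages uniform within each group range; sex Bernoulli(0.55 F); fasting
    plasma glucose ~4.8 (young) / ~5.2 (older) mmol/L.  Per-subject regional
    uptake multiplier = (1 + age_slope*(age-25)) * sex factor * lognormal
    noise; volume multiplier analogous.  Reproducible for a fixed seed.
    """
    spec = effect_spec if effect_spec is not None else default_effect_spec()
    return _sample_groups([("young", n_young), ("older", n_older)], spec, seed,
                          baseline, global_noise_sd)


def sample_clinical_cohort(n_control=20, n_mci=20, n_ad=20, effect_spec=None,
                           seed=0, baseline=None, global_noise_sd=GLOBAL_NOISE_SD):
    """Sample the control/MCI/AD cohort with graded planted hypometabolism."""
    spec = effect_spec if effect_spec is not None else clinical_effect_spec()
    return _sample_groups(
        [("control", n_control), ("MCI", n_mci), ("AD", n_ad)], spec, seed, baseline,
        global_noise_sd,
    )
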