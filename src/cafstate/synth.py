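"""Seeded synthetic-data generators for every pipeline input.

Each generator is a pure function of its arguments (including the seed)
and returns ground truth alongside the data, so every downstream stage can
be exercised and validated without any external dataset:

* 3D two-channel volumes containing spherical, prolate (spindle-like) and
  dendritic cells with a nuclei channel;
* negative-binomial scRNA-seq counts with four CAF subsets (myCAF,
  IFN-iCAF, IL-iCAF, adipoCAF) and planted subset markers;
* RT-qPCR Ct tables with planted log2 effects;
* ligand-receptor output tables in the three method dialects with planted
  true interactions;
* bimodal per-cell immunofluorescence measurement tables;
* survival cohorts with exponential event times and uniform censoring.

Noise models are deliberately the simplest that carry the structure the
analysis stages assume: Gaussian for imaging intensities and Ct values,
negative binomial for counts, exponential event times with independent
uniform censoring. No optics (PSF), doublets or batch effects are
emulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .morph3d import measure_cell, roundness, sphericity

__all__ = [
    "ShapeSpec",
    "CountsTruth",
    "SurvivalTruth",
    "CAF_SUBSETS",
    "gen_cell_volume",
    "gen_scrnaseq_counts",
    "gen_qpcr_table",
    "gen_lri_outputs",
    "gen_cell_marker_table",
    "gen_survival_cohort",
]

CAF_SUBSETS = ("myCAF", "IFN-iCAF", "IL-iCAF", "adipoCAF")


# ---------------------------------------------------------------- volumes


@dataclass(frozen=True)
class ShapeSpec:
    """One synthetic cell: a ball, a prolate spheroid, or a dendritic cell
    (ball body plus axis-aligned cylindrical protrusions).

    Sizes are in voxels; ``semi_axes`` is (z, y, x) for prolate shapes and
    ignored otherwise. Protrusion length is measured outward from the ball
    surface.
    """

    kind: str
    center: tuple[float, float, float]
    radius: float = 10.0
    semi_axes: tuple[float, float, float] | None = None
    n_protrusions: int = 4
    protrusion_length: float = 12.0
    protrusion_width: float = 5.0
    intensity_mean: float = 200.0
    intensity_sd: float = 0.0
    has_nucleus: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("ball", "prolate", "dendritic"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.kind == "prolate":
            if self.semi_axes is None or any(a <= 0 for a in self.semi_axes):
                raise ValueError("prolate shapes need positive semi_axes")
        elif self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.kind == "dendritic" and (
            self.n_protrusions < 1 or self.protrusion_length <= 0 or self.protrusion_width <= 0
        ):
            raise ValueError("dendritic protrusion parameters must be positive")

    @property
    def minor_axis(self) -> float:
        if self.kind == "prolate":
            return min(self.semi_axes)
        return self.radius


def _coordinate_grids(shape):
    return np.meshgrid(*(np.arange(s, dtype=float) for s in shape), indexing="ij")


def _render_mask(spec: ShapeSpec, volume_shape) -> np.ndarray:
    zz, yy, xx = _coordinate_grids(volume_shape)
    cz, cy, cx = spec.center
    if spec.kind == "ball":
        return (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.radius**2
    if spec.kind == "prolate":
        a, b, c = spec.semi_axes
        return ((zz - cz) / a) ** 2 + ((yy - cy) / b) ** 2 + ((xx - cx) / c) ** 2 <= 1.0
    # dendritic: ball body plus cylinders along alternating coordinate axes
    mask = (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2 <= spec.radius**2
    coords = np.stack([zz, yy, xx])
    center = np.array([cz, cy, cx])
    half_w = spec.protrusion_width / 2.0
    for p in range(spec.n_protrusions):
        axis = p % 3
        sign = 1.0 if (p // 3) % 2 == 0 else -1.0
        direction = np.zeros(3)
        direction[axis] = sign
        rel = coords - center[:, None, None, None]
        along = rel[axis] * sign
        radial = np.sqrt(sum(rel[i] ** 2 for i in range(3) if i != axis))
        cylinder = (
            (along >= 0)
            & (along <= spec.radius + spec.protrusion_length)
            & (radial <= half_w)
        )
        mask |= cylinder
    return mask


def _ellipsoid_surface_area(a: float, b: float, c: float) -> float:
    """Closed form for spheroids (two equal axes); Thomsen approximation
    (p = 1.6075, error < 1.1%) otherwise."""
    axes = sorted((a, b, c), reverse=True)
    a, b, c = axes
    if np.isclose(a, b) and np.isclose(b, c):
        return 4.0 * np.pi * a**2
    if np.isclose(b, c):  # prolate, a > b = c
        e = np.sqrt(1.0 - (b / a) ** 2)
        return 2.0 * np.pi * b**2 * (1.0 + (a / (b * e)) * np.arcsin(e))
    if np.isclose(a, b):  # oblate, a = b > c
        e = np.sqrt(1.0 - (c / a) ** 2)
        return 2.0 * np.pi * a**2 * (1.0 + ((1.0 - e**2) / e) * np.arctanh(e))
    p = 1.6075
    return 4.0 * np.pi * ((a**p * b**p + a**p * c**p + b**p * c**p) / 3.0) ** (1.0 / p)


def _analytic_truth(spec: ShapeSpec, mask: np.ndarray, voxel_size: float) -> dict:
    """Truth shape metrics: closed form for balls and prolates, mesh-measured
    from the exact truth mask for dendritic cells (no tidy closed form for
    overlapping solids)."""
    s = voxel_size
    if spec.kind == "ball":
        r = spec.radius * s
        vol = 4.0 / 3.0 * np.pi * r**3
        sa = 4.0 * np.pi * r**2
        dia = 2.0 * r
    elif spec.kind == "prolate":
        a, b, c = (ax * s for ax in spec.semi_axes)
        vol = 4.0 / 3.0 * np.pi * a * b * c
        sa = _ellipsoid_surface_area(a, b, c)
        dia = 2.0 * max(a, b, c)
    else:
        labeled = mask.astype(np.int32)
        m = measure_cell(labeled, 1, spacing=(s, s, s))
        vol, sa, dia = m["volume"], m["surface_area"], m["diameter"]
    return {
        "kind": spec.kind,
        "volume": float(vol),
        "surface_area": float(sa),
        "diameter": float(dia),
        "sphericity": sphericity(vol, sa),
        "roundness": roundness(vol, dia),
    }


def gen_cell_volume(
    shape_specs: list[ShapeSpec],
    volume_shape: tuple[int, int, int] = (64, 96, 96),
    voxel_size: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 10.0,
    nucleus_intensity: float = 200.0,
    allow_overlap: bool = False,
    allow_truncation: bool = False,
) -> dict:
    """Render a two-channel volume (cytoskeleton + nuclei) from shape specs.

    The cytoskeleton channel paints each shape at its intensity over a dim
    background with additive Gaussian noise; the nuclei channel contains
    one ball of a quarter of each cell's minor axis at the cell centroid.
    Returns the two channels, per-cell truth masks (labelled volume), and a
    truth shape table computed from the specs, not from the images.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    masks = [_render_mask(spec, volume_shape) for spec in shape_specs]

    occupied = np.zeros(volume_shape, dtype=bool)
    for i, m in enumerate(masks):
        if not allow_overlap and (m & occupied).any():
            raise ValueError(f"shape {i} overlaps an earlier shape")
        if not allow_truncation:
            border = (
                m[0].any() or m[-1].any()
                or m[:, 0].any() or m[:, -1].any()
                or m[:, :, 0].any() or m[:, :, -1].any()
            )
            if border:
                raise ValueError(f"shape {i} does not fit inside the volume")
        occupied |= m

    cyto = np.full(volume_shape, background, dtype=float)
    nuclei = np.full(volume_shape, background, dtype=float)
    labels = np.zeros(volume_shape, dtype=np.int32)
    truths = []
    for i, (spec, m) in enumerate(zip(shape_specs, masks), start=1):
        cyto[m] = spec.intensity_mean
        labels[m] = i
        if spec.has_nucleus:
            nuc = ShapeSpec(kind="ball", center=spec.center,
                            radius=max(spec.minor_axis / 4.0, 1.0))
            nuclei[_render_mask(nuc, volume_shape)] = nucleus_intensity
        truths.append({"label": i, **_analytic_truth(spec, m, voxel_size)})
    if noise_sd > 0:
        cyto = cyto + rng.normal(0.0, noise_sd, volume_shape)
        nuclei = nuclei + rng.normal(0.0, noise_sd, volume_shape)

    return {
        "cytoskeleton": cyto,
        "nuclei": nuclei,
        "truth_labels": labels,
        "truth_masks": masks,
        "truth_shapes": pd.DataFrame(truths),
        "voxel_size": voxel_size,
        "seed": seed,
    }


# ----------------------------------------------------------------- counts


@dataclass
class CountsTruth:
    """Synthetic scRNA-seq counts with planted subset markers."""

    counts: pd.DataFrame  # genes x cells, non-negative integers
    labels: pd.Series  # subset per cell
    markers: dict[str, list[str]]  # planted marker genes per subset
    effect_log2fc: float
    dispersion: float
    seed: int


def gen_scrnaseq_counts(
    n_cells_per_subset: int = 50,
    n_genes: int = 1000,
    markers_per_subset: int = 25,
    effect_log2fc: float = 2.0,
    dispersion: float = 0.5,
    seed: int = 0,
    subsets: tuple[str, ...] = CAF_SUBSETS,
    base_mean: float = 5.0,
) -> CountsTruth:
    """Negative-binomial counts with subset-specific marker elevation.

    Marker genes of a subset have their NB mean scaled by 2**effect_log2fc
    in that subset only; all other genes are exchangeable across subsets.
    Gene-level base means are log-normal around ``base_mean``. The NB uses
    the (mean, dispersion) parameterisation with variance mu + dispersion *
    mu^2.
    """
    if effect_log2fc < 0:
        raise ValueError("effect_log2fc must be >= 0")
    if n_cells_per_subset < 2:
        raise ValueError("need at least 2 cells per subset")
    if markers_per_subset * len(subsets) > n_genes:
        raise ValueError("more planted markers than genes")
    rng = np.random.default_rng(seed)

    genes = np.array([f"G{i:05d}" for i in range(n_genes)])
    cells, labels = [], []
    for s in subsets:
        for i in range(n_cells_per_subset):
            cells.append(f"{s}_{i:03d}")
            labels.append(s)
    labels = pd.Series(labels, index=cells, name="subset")

    base = base_mean * rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)
    marker_idx = rng.choice(n_genes, size=markers_per_subset * len(subsets), replace=False)
    markers = {
        s: sorted(genes[marker_idx[i * markers_per_subset : (i + 1) * markers_per_subset]])
        for i, s in enumerate(subsets)
    }

    mu = np.tile(base[:, None], (1, len(cells)))
    for s in subsets:
        cols = (labels == s).to_numpy()
        rows = np.isin(genes, markers[s])
        mu[np.ix_(rows, cols)] *= 2.0**effect_log2fc

    if dispersion > 0:
        size = 1.0 / dispersion
        p = size / (size + mu)
        counts = rng.negative_binomial(size, p)
    else:
        counts = rng.poisson(mu)
    return CountsTruth(
        counts=pd.DataFrame(counts, index=genes, columns=cells),
        labels=labels,
        markers=markers,
        effect_log2fc=effect_log2fc,
        dispersion=dispersion,
        seed=seed,
    )


# ------------------------------------------------------------------- qPCR

DEFAULT_QPCR_PANEL = (
    "ACTA2", "COL1A1", "TAGLN", "IL6", "IL24", "CXCL8", "TMEM158", "RPL37A",
)


def gen_qpcr_table(
    conditions: list[str],
    effects_log2: dict[str, dict[str, float]] | None = None,
    gene_panel: tuple[str, ...] = DEFAULT_QPCR_PANEL,
    reference_gene: str = "RPL37A",
    ct_noise_sd: float = 0.2,
    n_replicates: int = 3,
    seed: int = 0,
    reference_ct: float = 20.0,
    baseline_log2_rel: float = -4.0,
) -> pd.DataFrame:
    """Ct table with planted per-condition log2 effects.

    Constructed so that -(Ct_gene - Ct_reference) equals the baseline
    relative expression plus the planted effect plus Gaussian noise:
    Ct_gene = Ct_ref - (baseline + effect + noise). ``effects_log2`` maps
    condition -> {gene: planted log2 shift}; unlisted genes shift by 0.
    """
    if reference_gene not in gene_panel:
        raise ValueError("reference gene must be in the panel")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    effects_log2 = effects_log2 or {}
    rng = np.random.default_rng(seed)
    rows = []
    for cond in conditions:
        cond_eff = effects_log2.get(cond, {})
        for rep in range(1, n_replicates + 1):
            rows.append(
                {"condition": cond, "replicate": rep, "gene": reference_gene,
                 "ct": reference_ct}
            )
            for gene in gene_panel:
                if gene == reference_gene:
                    continue
                noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd > 0 else 0.0
                rel = baseline_log2_rel + cond_eff.get(gene, 0.0) + noise
                rows.append(
                    {"condition": cond, "replicate": rep, "gene": gene,
                     "ct": reference_ct - rel}
                )
    return pd.DataFrame(rows, columns=["condition", "replicate", "gene", "ct"])


# -------------------------------------------------------------------- LRI


def gen_lri_outputs(
    true_interactions: list[tuple[str, str, str, str]],
    n_patients: int = 6,
    noise_rate: float = 0.0,
    seed: int = 0,
    decoys_per_true: int = 4,
) -> dict:
    """Three method-dialect LRI tables with planted true interactions.

    At noise_rate 0 every true interaction is significant in the
    CellPhoneDB dialect (p < 0.05), ranks in the NATMI top 20% of its
    receiver (exactly: ``decoys_per_true`` low-scoring decoys are emitted
    per true, so ceil(0.2 n) keeps the trues), and is significant in >= 3
    patients in the Scriabin dialect; every decoy violates all three rules.
    With noise_rate > 0, each true loses each method's evidence
    independently with that probability, and each decoy gains cpdb or
    scriabin evidence with that probability.
    """
    if n_patients < 3:
        raise ValueError("recurrence rule needs at least 3 patients")
    if not 0.0 <= noise_rate <= 1.0:
        raise ValueError("noise_rate must be in [0, 1]")
    if not true_interactions:
        raise ValueError("need at least one true interaction")
    rng = np.random.default_rng(seed)
    trues = [tuple(str(v).upper() for v in t) for t in true_interactions]

    decoys = []
    for i, (_, _, sender, receiver) in enumerate(trues):
        for d in range(decoys_per_true):
            decoys.append((f"DECOYLIG{i}_{d}", f"DECOYREC{i}_{d}", sender, receiver))

    patients = [f"P{p + 1}" for p in range(n_patients)]
    cpdb_rows, natmi_rows = [], []
    scriabin_rows: dict[str, list] = {p: [] for p in patients}

    def scriabin_detect(key, n_sig):
        order = rng.permutation(n_patients)
        for rank, pi in enumerate(order):
            p_val = rng.uniform(0.0, 0.04) if rank < n_sig else rng.uniform(0.06, 1.0)
            scriabin_rows[patients[pi]].append(
                {"ligand": key[0], "receptor": key[1], "sender": key[2],
                 "receiver": key[3], "p_value": p_val}
            )

    for key in trues:
        drop = rng.random(3) < noise_rate  # cpdb, natmi, scriabin
        cpdb_p = rng.uniform(0.06, 1.0) if drop[0] else rng.uniform(0.0, 0.04)
        cpdb_rows.append({"ligand": key[0], "receptor": key[1], "sender": key[2],
                          "receiver": key[3], "p_value": cpdb_p})
        if drop[1]:
            weight, spec = rng.uniform(0.1, 1.0), rng.uniform(0.1, 1.0)
        else:
            weight, spec = rng.uniform(10.0, 20.0), rng.uniform(10.0, 20.0)
        natmi_rows.append({"ligand": key[0], "receptor": key[1], "sender": key[2],
                           "receiver": key[3], "weight": weight, "specificity": spec})
        n_sig = 2 if drop[2] else int(rng.integers(3, n_patients + 1))
        scriabin_detect(key, n_sig)

    for key in decoys:
        gain = rng.random(2) < noise_rate  # cpdb, scriabin
        cpdb_p = rng.uniform(0.0, 0.04) if gain[0] else rng.uniform(0.06, 1.0)
        cpdb_rows.append({"ligand": key[0], "receptor": key[1], "sender": key[2],
                          "receiver": key[3], "p_value": cpdb_p})
        natmi_rows.append({"ligand": key[0], "receptor": key[1], "sender": key[2],
                           "receiver": key[3], "weight": rng.uniform(0.1, 1.0),
                           "specificity": rng.uniform(0.1, 1.0)})
        n_sig = int(rng.integers(3, n_patients + 1)) if gain[1] else int(rng.integers(0, 3))
        scriabin_detect(key, n_sig)

    return {
        "cpdb": pd.DataFrame(cpdb_rows),
        "natmi": pd.DataFrame(natmi_rows),
        "scriabin": {p: pd.DataFrame(rows) for p, rows in scriabin_rows.items()},
        "truth": {"true": trues, "decoy": decoys},
        "seed": seed,
    }


# --------------------------------------------------------- marker tables


def gen_cell_marker_table(
    n_cells_per_group: int = 1000,
    marker_modes: tuple[float, float] = (100.0, 300.0),
    marker_sd: float = 10.0,
    mode_weights: tuple[float, float] = (0.6, 0.4),
    shift_percent: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-cell immunofluorescence table with bimodal marker intensities.

    Columns: cell_id, group (control/treated), nucleus_area, dapi_total,
    pdpn_total, marker_total. The treated group's marker intensities are
    scaled by (1 + shift_percent/100). The marker mixture puts 60% of the
    mass on the low mode by default so the group median sits inside a mode
    and the percentage-change statistic is stable.
    """
    rng = np.random.default_rng(seed)
    lo, hi = marker_modes
    w_lo, w_hi = mode_weights
    if not np.isclose(w_lo + w_hi, 1.0):
        raise ValueError("mode weights must sum to 1")
    rows = []
    for group in ("control", "treated"):
        modes = rng.choice([lo, hi], size=n_cells_per_group, p=[w_lo, w_hi])
        marker = np.clip(rng.normal(modes, marker_sd), 0.0, None)
        if group == "treated":
            marker = marker * (1.0 + shift_percent / 100.0)
        pdpn_modes = rng.choice([lo, hi], size=n_cells_per_group, p=[0.3, 0.7])
        pdpn = np.clip(rng.normal(pdpn_modes, marker_sd), 0.0, None)
        area = np.clip(rng.normal(50.0, 8.0, n_cells_per_group), 1.0, None)
        dapi = np.clip(rng.normal(1000.0, 100.0, n_cells_per_group), 1.0, None)
        for i in range(n_cells_per_group):
            rows.append(
                {"cell_id": f"{group}_{i:05d}", "group": group,
                 "nucleus_area": area[i], "dapi_total": dapi[i],
                 "pdpn_total": pdpn[i], "marker_total": marker[i]}
            )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------- survival


@dataclass
class SurvivalTruth:
    """Synthetic survival cohort with known per-stratum hazards."""

    table: pd.DataFrame  # patient, time, event, stratum
    hazards: dict[str, float]
    censor_rate: float
    seed: int


def _uniform_censor_bound(hazard: float, censor_rate: float) -> float:
    """Upper bound b of U(0, b) censoring giving P(censored) = censor_rate
    against Exp(hazard) event times: solves (1 - exp(-h b)) / (h b) = rate."""
    f = lambda b: (1.0 - np.exp(-hazard * b)) / (hazard * b) - censor_rate
    return brentq(f, 1e-9 / hazard, 1e6 / hazard)


def gen_survival_cohort(
    n_per_stratum: int = 100,
    strata_hazards: dict[str, float] | None = None,
    censor_rate: float = 0.2,
    seed: int = 0,
) -> SurvivalTruth:
    """Exponential event times with independent uniform censoring.

    ``strata_hazards`` maps stratum name -> hazard (events per unit time);
    the uniform censoring bound is solved per stratum so the expected
    censored fraction equals ``censor_rate``.
    """
    if strata_hazards is None:
        strata_hazards = {"low": 0.03, "medium": 0.01, "high": 0.02}
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    rows = []
    for stratum in sorted(strata_hazards):
        h = strata_hazards[stratum]
        if h <= 0:
            raise ValueError("hazards must be positive")
        event_t = rng.exponential(1.0 / h, size=n_per_stratum)
        if censor_rate > 0:
            b = _uniform_censor_bound(h, censor_rate)
            censor_t = rng.uniform(0.0, b, size=n_per_stratum)
        else:
            censor_t = np.full(n_per_stratum, np.inf)
        time = np.minimum(event_t, censor_t)
        event = (event_t <= censor_t).astype(int)
        for i in range(n_per_stratum):
            rows.append(
                {"patient": f"{stratum}_{i:04d}", "time": float(time[i]),
                 "event": int(event[i]), "stratum": stratum}
            )
    return SurvivalTruth(
        table=pd.DataFrame(rows), hazards=dict(strata_hazards),
        censor_rate=censor_rate, seed=seed,
    )
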