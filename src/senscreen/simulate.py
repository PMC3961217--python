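"""Synthetic-data generators for the senescence-screen pipeline.

Everything the downstream stages consume — plate maps, per-cell intensity
tables, rendered two-channel well images, UTR sequences with planted miRNA
seed sites, qPCR Ct tables and gene-expression matrices — can be generated
here together with its ground truth, so the whole pipeline is testable
without any external data.

The screen generator emulates a 384-well high-content screen of an
arrayed pre-miR library in oncogene-induced-senescence fibroblasts:
library miRNAs in quadruplicate wells, per-plate control wells (scrambled
with and without senescence induction, plus three siRNA controls), six
imaged fields per well with roughly 100 cells each, and a per-cell
two-channel readout (nuclear stain + senescence-marker immunofluorescence).
A planted "hit" multiplies the well's probability of a cell being
marker-positive; plate-to-plate and well-to-well variation is added on the
logit of that probability so fractions stay in range.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

__all__ = [
    "CONTROL_ROLES",
    "SimulationConfig",
    "SimulationTruth",
    "make_plate_maps",
    "simulate_well",
    "simulate_screen_cells",
    "render_well_images",
    "simulate_utrs",
    "simulate_qpcr",
    "simulate_expression",
]

#: Control roles present on every plate. SCR is the scrambled control with
#: senescence induced; SCR_uninduced is the scrambled control without
#: induction (staining/technical control); the three siRNA controls knock
#: down BMI1, p16 and JMJD3 respectively.
CONTROL_ROLES = ("SCR", "SCR_uninduced", "BMI1i", "p16i", "JMJD3i")

# Intensity model (arbitrary fluorescence units). Log-normal components:
# every nucleus is bright in the nuclear channel; the marker channel is a
# two-component mixture so that positive and negative cells are separable
# by a single threshold.
NUCLEAR_LOG_MEAN = np.log(500.0)
NUCLEAR_LOG_SD = 0.15
MARKER_NEG_LOG_MEAN = np.log(40.0)
MARKER_POS_LOG_MEAN = np.log(600.0)
MARKER_LOG_SD = 0.20

_LOGIT_EPS = 1e-9


def _default_control_effects() -> dict[str, float]:
    # Multipliers on the induced positive fraction. BMI1 and JMJD3
    # knockdown enhance marker induction; p16 knockdown strongly reduces
    # it (partial knockdown, not a complete null).
    return {"SCR": 1.0, "SCR_uninduced": 1.0, "BMI1i": 1.7, "JMJD3i": 1.5, "p16i": 0.25}


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic screen.

    Defaults reproduce the screen's reported design: a 471-member pre-miR
    library in quadruplicate on 384-well plates, six images per well with
    ~100 cells each, up-hits increasing the percent-positive ~2.25-fold
    and down-hits decreasing it 5–10-fold.
    """

    n_library_mirnas: int = 471
    replicates_per_mirna: int = 4
    wells_per_plate: int = 384
    n_plates: int | None = None  # None: smallest number that fits the library
    images_per_well: int = 6
    cells_per_image_mean: float = 100.0
    baseline_positive_fraction: float = 0.30
    uninduced_positive_fraction: float = 0.02
    up_hit_fold: float = 2.25
    down_hit_fold_range: tuple[float, float] = (5.0, 10.0)
    hit_fraction: float = 23 / 471
    up_hit_share: float = 16 / 23
    plate_noise_sd: float = 0.15
    well_noise_sd: float = 0.10
    control_wells_per_role: int = 8
    control_effects: Mapping[str, float] = field(default_factory=_default_control_effects)
    rng_seed: int = 0

    # ---- derived quantities -------------------------------------------------

    @property
    def control_wells_per_plate(self) -> int:
        return self.control_wells_per_role * len(CONTROL_ROLES)

    @property
    def library_wells_per_plate(self) -> int:
        return self.wells_per_plate - self.control_wells_per_plate

    def required_plates(self) -> int:
        total_library = self.n_library_mirnas * self.replicates_per_mirna
        per_plate = self.library_wells_per_plate
        if per_plate <= 0:
            raise ValueError("controls alone exceed wells_per_plate")
        return -(-total_library // per_plate)

    def resolved_plates(self) -> int:
        return self.required_plates() if self.n_plates is None else self.n_plates

    def validate(self) -> None:
        for name in ("baseline_positive_fraction", "uninduced_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} not in [0, 1]")
        if not 0.0 <= self.hit_fraction <= 1.0:
            raise ValueError("hit_fraction not in [0, 1]")
        lo, hi = self.down_hit_fold_range
        if self.up_hit_fold <= 0 or lo <= 0 or hi <= 0 or hi < lo:
            raise ValueError("fold parameters must be positive (range low <= high)")
        if self.plate_noise_sd < 0 or self.well_noise_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        for n in (
            "n_library_mirnas",
            "replicates_per_mirna",
            "wells_per_plate",
            "images_per_well",
            "control_wells_per_role",
        ):
            if getattr(self, n) < 1:
                raise ValueError(f"{n} must be >= 1")
        if self.resolved_plates() < self.required_plates():
            raise ValueError(
                f"capacity: {self.n_library_mirnas} miRNAs x "
                f"{self.replicates_per_mirna} replicates + controls do not fit in "
                f"{self.resolved_plates()} plates of {self.wells_per_plate} wells"
            )

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class SimulationTruth:
    """Ground truth written by the generators, one field per downstream
    recovery test."""

    #: columns: sample, effect, direction in {up, down, none}
    mirna_effects: pd.DataFrame | None = None
    #: columns: plate, logit_shift
    plate_effects: pd.DataFrame | None = None
    #: list of (transcript_id, start, end, site_type)
    utr_sites: list[tuple[str, int, int, str]] = field(default_factory=list)
    #: columns: gene, log2_fold_change, affected
    gene_fold_changes: pd.DataFrame | None = None
    #: true treated/control expression ratios keyed by assay label
    qpcr_ratios: dict[str, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# plate maps
# ---------------------------------------------------------------------------

_ROW_LETTERS = "ABCDEFGHIJKLMNOP"


def well_names(wells_per_plate: int) -> list[str]:
    """Row-major well coordinates (A01, A02, ...) for standard plate sizes."""
    for n_rows, n_cols in ((16, 24), (8, 12), (4, 6)):
        if wells_per_plate == n_rows * n_cols:
            return [
                f"{_ROW_LETTERS[r]}{c + 1:02d}"
                for r in range(n_rows)
                for c in range(n_cols)
            ]
    return [f"W{i + 1:03d}" for i in range(wells_per_plate)]


def make_plate_maps(config: SimulationConfig) -> tuple[pd.DataFrame, SimulationTruth]:
    """Lay out the screen and draw its ground truth.

    Returns a plate-map table with columns (plate, well, sample, role,
    replicate) and a :class:`SimulationTruth` holding per-miRNA effect
    multipliers and per-plate logit shifts. Library miRNAs are placed in
    consecutive wells so replicates land on the same plate whenever the
    per-plate library capacity is a multiple of the replicate count.
    """
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    n_plates = config.resolved_plates()
    names = well_names(config.wells_per_plate)

    samples = [f"miR-{i + 1:03d}" for i in range(config.n_library_mirnas)]

    # true effects: a hit_fraction of miRNAs are up- or down-hits
    n_hits = int(round(config.hit_fraction * config.n_library_mirnas))
    n_up = int(round(config.up_hit_share * n_hits))
    hit_idx = rng.choice(config.n_library_mirnas, size=n_hits, replace=False)
    effects = np.ones(config.n_library_mirnas)
    direction = np.array(["none"] * config.n_library_mirnas, dtype=object)
    up_idx = hit_idx[:n_up]
    down_idx = hit_idx[n_up:]
    effects[up_idx] = config.up_hit_fold
    lo, hi = config.down_hit_fold_range
    effects[down_idx] = 1.0 / rng.uniform(lo, hi, size=len(down_idx))
    direction[up_idx] = "up"
    direction[down_idx] = "down"

    rows: list[tuple[int, str, str, str, int]] = []
    lib_queue = [
        (s, r) for s in samples for r in range(config.replicates_per_mirna)
    ]
    pos = 0
    for plate in range(1, n_plates + 1):
        cursor = 0
        for role in CONTROL_ROLES:
            for r in range(config.control_wells_per_role):
                rows.append((plate, names[cursor], role, role, r))
                cursor += 1
        while cursor < config.wells_per_plate and pos < len(lib_queue):
            s, r = lib_queue[pos]
            rows.append((plate, names[cursor], s, "library", r))
            cursor += 1
            pos += 1
    if pos < len(lib_queue):  # validate() should have caught this
        raise ValueError("capacity: library wells exceed available plate space")

    platemap = pd.DataFrame(
        rows, columns=["plate", "well", "sample", "role", "replicate"]
    )
    truth = SimulationTruth(
        mirna_effects=pd.DataFrame(
            {"sample": samples, "effect": effects, "direction": direction}
        ),
        plate_effects=pd.DataFrame(
            {
                "plate": np.arange(1, n_plates + 1),
                "logit_shift": rng.normal(0.0, config.plate_noise_sd, n_plates),
            }
        ),
    )
    return platemap, truth


# ---------------------------------------------------------------------------
# per-well cell tables
# ---------------------------------------------------------------------------


def positive_probability(
    effect: float,
    config: SimulationConfig,
    role: str = "library",
    plate_shift: float = 0.0,
    well_shift: float = 0.0,
) -> float:
    """Probability that a cell in this well is marker-positive.

    The clean value is ``clamp(baseline * effect, 0, 1)`` (uninduced
    scrambled wells use ``uninduced_positive_fraction`` regardless of
    effect); plate- and well-level variation is added on the logit scale
    so noisy values remain valid probabilities.
    """
    if effect <= 0:
        raise ValueError("effect must be > 0")
    if role == "SCR_uninduced":
        p = config.uninduced_positive_fraction
    else:
        p = min(max(config.baseline_positive_fraction * effect, 0.0), 1.0)
    shift = plate_shift + well_shift
    if shift == 0.0:
        return p
    p = min(max(p, _LOGIT_EPS), 1.0 - _LOGIT_EPS)
    return float(expit(logit(p) + shift))


def _sample_centroids(
    n: int,
    shape: tuple[int, int],
    min_separation: float,
    margin: float,
    rng: np.random.Generator,
    max_attempts: int = 200_000,
) -> np.ndarray:
    """Dart-throwing sampler for nucleus centres with a hard minimum
    pairwise distance. Raises if the requested count cannot be placed."""
    pts: list[np.ndarray] = []
    lo = np.array([margin, margin])
    hi = np.array([shape[0] - margin, shape[1] - margin])
    if np.any(hi <= lo):
        raise ValueError("image too small for requested margin")
    arr = np.empty((0, 2))
    attempts = 0
    while len(pts) < n:
        if attempts >= max_attempts:
            raise ValueError(
                f"could not place {n} nuclei with separation {min_separation} "
                f"in a {shape} image"
            )
        cand = rng.uniform(lo, hi)
        if len(pts) == 0 or np.all(
            np.sum((arr - cand) ** 2, axis=1) >= min_separation**2
        ):
            pts.append(cand)
            arr = np.asarray(pts)
        attempts += 1
    return arr


def simulate_well(
    effect: float,
    config: SimulationConfig,
    rng: np.random.Generator,
    role: str = "library",
    plate_shift: float = 0.0,
    with_positions: bool = False,
    image_shape: tuple[int, int] = (360, 360),
    min_separation: float = 12.0,
    margin: float = 12.0,
) -> pd.DataFrame:
    """Simulate the cells of one well across ``images_per_well`` fields.

    Returns a table with one row per cell: field, nuclear and marker
    intensities, the true positive flag, and (optionally) centroids
    placed with a minimum pairwise separation so the well can be rendered
    to images.
    """
    well_shift = rng.normal(0.0, config.well_noise_sd) if config.well_noise_sd else 0.0
    p = positive_probability(effect, config, role, plate_shift, well_shift)
    frames = []
    for f in range(config.images_per_well):
        n = int(rng.poisson(config.cells_per_image_mean))
        pos = rng.random(n) < p
        nuclear = rng.lognormal(NUCLEAR_LOG_MEAN, NUCLEAR_LOG_SD, n)
        marker = rng.lognormal(
            np.where(pos, MARKER_POS_LOG_MEAN, MARKER_NEG_LOG_MEAN), MARKER_LOG_SD
        )
        df = pd.DataFrame(
            {
                "field": f,
                "nuclear_intensity": nuclear,
                "marker_intensity": marker,
                "true_positive": pos,
            }
        )
        if with_positions:
            cent = _sample_centroids(n, image_shape, min_separation, margin, rng)
            df["row"] = cent[:, 0]
            df["col"] = cent[:, 1]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def simulate_screen_cells(
    platemap: pd.DataFrame,
    truth: SimulationTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Vectorised cell-table generator for a whole screen.

    Produces the same per-cell model as :func:`simulate_well` for every
    well in the plate map at once (no centroids), which keeps a full
    471-miRNA quadruplicate screen with ~1.3 million cells fast enough
    for repeated simulation studies.
    """
    effects = dict(
        zip(truth.mirna_effects["sample"], truth.mirna_effects["effect"])
    )
    plate_shift = dict(
        zip(truth.plate_effects["plate"], truth.plate_effects["logit_shift"])
    )
    wells = platemap.reset_index(drop=True)
    n_wells = len(wells)

    eff = np.array(
        [
            effects.get(s, config.control_effects.get(s, 1.0))
            for s in wells["sample"]
        ]
    )
    well_shift = rng.normal(0.0, config.well_noise_sd, n_wells)
    p_well = np.array(
        [
            positive_probability(
                eff[i],
                config,
                role=wells["role"].iloc[i],
                plate_shift=plate_shift[wells["plate"].iloc[i]],
                well_shift=well_shift[i],
            )
            for i in range(n_wells)
        ]
    )

    counts = rng.poisson(config.cells_per_image_mean, (n_wells, config.images_per_well))
    flat_counts = counts.ravel()
    total = int(flat_counts.sum())
    unit = np.repeat(np.arange(n_wells * config.images_per_well), flat_counts)
    well_idx = unit // config.images_per_well
    field_idx = unit % config.images_per_well

    pos = rng.random(total) < p_well[well_idx]
    nuclear = rng.lognormal(NUCLEAR_LOG_MEAN, NUCLEAR_LOG_SD, total)
    marker = rng.lognormal(
        np.where(pos, MARKER_POS_LOG_MEAN, MARKER_NEG_LOG_MEAN), MARKER_LOG_SD
    )
    return pd.DataFrame(
        {
            "plate": wells["plate"].to_numpy()[well_idx],
            "well": pd.Categorical(wells["well"].to_numpy()[well_idx]),
            "sample": pd.Categorical(wells["sample"].to_numpy()[well_idx]),
            "role": pd.Categorical(wells["role"].to_numpy()[well_idx]),
            "field": field_idx,
            "nuclear_intensity": nuclear,
            "marker_intensity": marker,
            "true_positive": pos,
        }
    )


# ---------------------------------------------------------------------------
# image rendering
# ---------------------------------------------------------------------------


def render_well_images(
    cells: pd.DataFrame,
    image_shape: tuple[int, int] = (360, 360),
    blob_sigma: float = 3.0,
    background: float = 100.0,
    read_noise_sd: float = 5.0,
    rng: np.random.Generator | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Render a well's cell table to two-channel 16-bit images.

    Each nucleus becomes an isotropic Gaussian blob on a constant-plus-
    noise background; channel 1 amplitude is the cell's nuclear intensity,
    channel 2 amplitude its marker intensity. Returns one (nuclear,
    marker) uint16 pair per field, in field order.
    """
    if "row" not in cells.columns:
        raise ValueError("cell table has no centroids; simulate with with_positions=True")
    rng = np.random.default_rng() if rng is None else rng
    out = []
    fields = sorted(cells["field"].unique()) if len(cells) else [0]
    half = int(np.ceil(4 * blob_sigma))
    span = np.arange(-half, half + 1)
    gy = np.exp(-(span**2) / (2 * blob_sigma**2))
    patch = np.outer(gy, gy)
    for f in fields:
        sub = cells[cells["field"] == f]
        chans = []
        for col in ("nuclear_intensity", "marker_intensity"):
            img = np.full(image_shape, background, dtype=float)
            img += rng.normal(0.0, read_noise_sd, image_shape)
            for _, cell in sub.iterrows():
                r, c = int(round(cell["row"])), int(round(cell["col"]))
                r0, r1 = max(r - half, 0), min(r + half + 1, image_shape[0])
                c0, c1 = max(c - half, 0), min(c + half + 1, image_shape[1])
                img[r0:r1, c0:c1] += (
                    cell[col]
                    * patch[r0 - r + half : r1 - r + half, c0 - c + half : c1 - c + half]
                )
            chans.append(np.clip(np.round(img), 0, 65535).astype(np.uint16))
        out.append((chans[0], chans[1]))
    return out


# ---------------------------------------------------------------------------
# UTR sequences with planted seed sites
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _site_string(seed7: str, site_type: str) -> str:
    """UTR sense-strand sequence of a seed-match site of the given type."""
    rc7 = _revcomp(seed7)  # complement of miRNA positions 2-8, 5'->3' on the UTR
    rc6 = rc7[1:]  # complement of positions 2-7
    if site_type == "8mer":
        return rc7 + "A"
    if site_type == "7mer-m8":
        return rc7
    if site_type == "7mer-A1":
        return rc6 + "A"
    if site_type == "6mer":
        return rc6
    raise ValueError(f"unknown site type {site_type!r}")


def simulate_utrs(
    n_transcripts: int,
    lengths: int | Sequence[int],
    planted_sites: Sequence[tuple[int, int, str]],
    mirna_seed: str,
    rng: np.random.Generator,
    background_freqs: Mapping[str, float] | None = None,
    clean_background: bool = True,
    transcript_prefix: str = "tx",
) -> tuple[dict[str, str], SimulationTruth]:
    """Generate UTR sequences with seed-match sites planted at known spots.

    ``planted_sites`` is a list of (transcript index, position, site type).
    The exact site sequence for the requested type is written at each
    position and its flanking bases are adjusted so the site scans as
    exactly that type (e.g. a planted 7mer-m8 is never followed by an A,
    which would upgrade it to an 8mer). With ``clean_background`` the
    background is re-drawn wherever it accidentally contains the seed's
    6-mer core, so the planted sites are the only sites present.
    """
    seed7 = mirna_seed.upper().replace("U", "T")
    if len(seed7) != 7 or set(seed7) - set("ACGT"):
        raise ValueError("mirna_seed must be the 7-nt seed (positions 2-8)")
    rc7 = _revcomp(seed7)
    rc6 = rc7[1:]
    m8c = rc7[0]
    # a site string must contain the 6-mer core exactly once, at its
    # canonical offset, or planted-site truth would be ambiguous
    for stype, offset in (("8mer", 1), ("7mer-m8", 1), ("7mer-A1", 0), ("6mer", 0)):
        s = _site_string(seed7, stype)
        if [i for i in range(len(s) - 5) if s[i : i + 6] == rc6] != [offset]:
            raise ValueError("seed core is self-overlapping; choose a non-periodic seed")

    if isinstance(lengths, int):
        lengths = [lengths] * n_transcripts
    if len(lengths) != n_transcripts:
        raise ValueError("lengths must match n_transcripts")
    freqs = background_freqs or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    bases = np.array(list("ACGT"))
    pvec = np.array([freqs.get(b, 0.0) for b in "ACGT"], dtype=float)
    pvec = pvec / pvec.sum()

    # planted-site extents (with a 1-nt guard for flank adjustment)
    by_tx: dict[int, list[tuple[int, int, str]]] = {}
    for tx, pos, stype in planted_sites:
        site = _site_string(seed7, stype)
        if pos < 0 or pos + len(site) > lengths[tx]:
            raise ValueError(
                f"planted {stype} at {pos} does not fit transcript {tx} "
                f"(length {lengths[tx]})"
            )
        by_tx.setdefault(tx, []).append((pos, pos + len(site), stype))
    for tx, sites in by_tx.items():
        sites.sort()
        for (s0, e0, t0), (s1, e1, t1) in zip(sites, sites[1:]):
            if s1 < e0 + 1:  # guard base between adjacent sites
                raise ValueError(
                    f"planted sites overlap on transcript {tx}: "
                    f"({s0},{e0},{t0}) vs ({s1},{e1},{t1})"
                )

    records: dict[str, str] = {}
    truth_sites: list[tuple[str, int, int, str]] = []
    non_a = [b for b in "CGT"]
    not_m8 = [b for b in "ACGT" if b != m8c]

    for tx in range(n_transcripts):
        L = lengths[tx]
        seq = rng.choice(bases, size=L, p=pvec)
        tx_id = f"{transcript_prefix}{tx + 1:04d}"
        planted = sorted(by_tx.get(tx, []))
        protected = np.zeros(L, dtype=bool)
        canonical_cores: set[int] = set()
        for start, end, stype in planted:
            site = _site_string(seed7, stype)
            seq[start:end] = list(site)
            protected[start:end] = True
            canonical_cores.add(start + 1 if stype in ("8mer", "7mer-m8") else start)
            # flank guards so the site types exactly as requested
            if stype in ("7mer-m8",) and end < L and seq[end] == "A":
                seq[end] = rng.choice(non_a)
            if stype in ("7mer-A1", "6mer") and start > 0 and seq[start - 1] == m8c:
                seq[start - 1] = rng.choice(not_m8)
            if stype == "6mer" and end < L and seq[end] == "A":
                seq[end] = rng.choice(non_a)
            if start > 0:
                protected[start - 1] = True
            if end < L:
                protected[end] = True
            truth_sites.append((tx_id, start, end, stype))
        if clean_background:
            for _ in range(200):
                s = "".join(seq)
                dirty = []
                i = s.find(rc6)
                while i != -1:
                    if i not in canonical_cores:
                        dirty.append(i)
                    i = s.find(rc6, i + 1)
                if not dirty:
                    break
                for i in dirty:
                    free = [j for j in range(i, i + 6) if not protected[j]]
                    if not free:
                        raise RuntimeError(
                            f"accidental seed core inside planted bases at {i}"
                        )
                    for j in free:
                        seq[j] = rng.choice(bases, p=pvec)
            else:
                raise RuntimeError("failed to produce a clean background")
        records[tx_id] = "".join(seq)

    truth = SimulationTruth(utr_sites=truth_sites)
    return records, truth


# ---------------------------------------------------------------------------
# qPCR Ct tables
# ---------------------------------------------------------------------------


def simulate_qpcr(
    true_ratio: float,
    n_replicates: int = 3,
    ct_noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    reference_ct: float = 20.0,
    target_control_ct: float = 25.0,
) -> pd.DataFrame:
    """Generate a Ct table whose expected 2^-ddCt equals ``true_ratio``.

    Amplification efficiency is assumed to be exactly 2, so a treated/
    control expression ratio r shifts the treated target Ct by -log2(r)
    cycles relative to its reference-normalised control baseline.
    Gaussian noise of SD ``ct_noise_sd`` is added independently to every
    Ct measurement.
    """
    if true_ratio <= 0:
        raise ValueError("true_ratio must be > 0")
    rng = np.random.default_rng() if rng is None else rng
    base = {
        ("control", "reference"): reference_ct,
        ("treated", "reference"): reference_ct,
        ("control", "target"): target_control_ct,
        ("treated", "target"): target_control_ct - np.log2(true_ratio),
    }
    rows = []
    for (condition, role), ct in base.items():
        for rep in range(n_replicates):
            noise = rng.normal(0.0, ct_noise_sd) if ct_noise_sd else 0.0
            rows.append((condition, role, rep, ct + noise))
    return pd.DataFrame(rows, columns=["condition", "role", "replicate", "ct"])


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


def simulate_expression(
    n_genes: int,
    fold_changes: Mapping[str, float] | None = None,
    n_per_group: int = 3,
    dispersion: float = 0.15,
    base_log2_mean: float = 7.0,
    base_log2_sd: float = 2.0,
    rng: np.random.Generator | None = None,
    gene_prefix: str = "gene",
) -> tuple[pd.DataFrame, pd.Series, SimulationTruth]:
    """Log-normal expression matrix for a two-group comparison.

    ``fold_changes`` maps gene ids to treated/control fold changes on the
    linear scale (genes not listed are unaffected). Returns the genes x
    samples matrix (linear scale), a sample -> group series, and the
    truth table of planted log2 fold changes.
    """
    if n_per_group < 2:
        raise ValueError("need >= 2 replicates per group")
    rng = np.random.default_rng() if rng is None else rng
    genes = [f"{gene_prefix}{i + 1:04d}" for i in range(n_genes)]
    fold_changes = fold_changes or {}
    unknown = set(fold_changes) - set(genes)
    if unknown:
        raise ValueError(f"fold_changes reference unknown genes: {sorted(unknown)[:5]}")
    l2fc = np.array([np.log2(fold_changes.get(g, 1.0)) for g in genes])

    base = rng.normal(base_log2_mean, base_log2_sd, n_genes)
    samples = [f"control_{i + 1}" for i in range(n_per_group)] + [
        f"treated_{i + 1}" for i in range(n_per_group)
    ]
    groups = pd.Series(
        ["control"] * n_per_group + ["treated"] * n_per_group, index=samples, name="group"
    )
    log2_expr = np.empty((n_genes, 2 * n_per_group))
    for j, s in enumerate(samples):
        shift = l2fc if groups[s] == "treated" else 0.0
        log2_expr[:, j] = base + shift + rng.normal(0.0, dispersion, n_genes)
    expr = pd.DataFrame(2.0**log2_expr, index=genes, columns=samples)
    truth = SimulationTruth(
        gene_fold_changes=pd.DataFrame(
            {"gene": genes, "log2_fold_change": l2fc, "affected": l2fc != 0.0}
        )
    )
    return expr, groups, truth
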