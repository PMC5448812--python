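"""Seeded generators for every data type the pipeline consumes.

Each generator emulates one experimental data stream with a known ground
truth, so every estimator in the package can be validated end to end without
external data:

* :func:`simulate_tetrads` -- spore-autonomous fluorescence tetrads from a
  Poisson crossover model with random chromatid choice (no crossover or
  chromatid interference) and optional MI nondisjunction;
* :func:`simulate_lane_set` -- western-blot lane traces of N-terminal
  cleavage fragments plus a marker-ladder lane, under a smooth log-linear
  migration law (deliberately not the quartic used for calibration, so
  calibration robustness is exercised);
* :func:`simulate_afm_field` -- AFM height maps of Gaussian-cap particles
  with exactly known analytic volumes;
* :func:`simulate_titration` -- Hill or Michaelis-Menten response curves
  with additive Gaussian noise;
* :func:`simulate_reversion_assay` -- Poisson revertant counts per culture.

All generators are bit-reproducible for a fixed seed and return a
machine-readable truth record sufficient to score the matching estimator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .afm import HeightMap, classify_volume
from .footprint import LaneProfile, MarkerLadder, ProteinRecord
from .kinetics import TitrationSeries, hill_bound, michaelis_menten
from .tetrads import write_tetrad_tsv

__all__ = [
    "MAGICMARK_XP_KDA",
    "TetradSimulation",
    "LaneSimulation",
    "AFMSimulation",
    "TitrationSimulation",
    "simulate_tetrads",
    "simulate_lane_set",
    "simulate_afm_field",
    "simulate_titration",
    "simulate_reversion_assay",
]

#: MagicMark XP-style western ladder (kDa).
MAGICMARK_XP_KDA = (220.0, 120.0, 100.0, 80.0, 60.0, 50.0, 40.0, 30.0, 20.0)

#: Default simulated ladder: the 20-120 kDa bands. A quartic in MW fitted
#: across the sparse 120-220 kDa gap need not stay monotone, so calibration
#: uses the bands spanning the fragment range, as one would on a real gel.
DEFAULT_LADDER_KDA = MAGICMARK_XP_KDA[1:]


#: Study conditions for the tetrad simulator, per strain. Wild-type map
#: distances are the printed values for the two test intervals; deletion
#: strains retain ~60-70% of wild-type crossovers (here 60%, rounded) and
#: show elevated MI nondisjunction (1.15% for mlh1-null, 2.73% for
#: mlh3-null; wild type ~0.1%).
WT_TETRAD_CONDITIONS = {"d1_cm": 11.63, "d2_cm": 4.22, "nd_prob": 0.001}
MLH1_DELETION_TETRAD_CONDITIONS = {"d1_cm": 7.0, "d2_cm": 2.5, "nd_prob": 0.0115}
MLH3_DELETION_TETRAD_CONDITIONS = {"d1_cm": 7.0, "d2_cm": 2.5, "nd_prob": 0.0273}


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Tetrads
# ---------------------------------------------------------------------------


@dataclass
class TetradSimulation:
    """Simulated tetrads: fluorescence patterns plus generative truth."""

    patterns: np.ndarray  # (n, 4, 3) bool
    truth: pd.DataFrame  # nd, n_co1, n_co2, interval1, interval2
    params: dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_tetrad_tsv(self.patterns, outdir / "tetrads.tsv")
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.params, fh, indent=1)


_TYPE_NAMES = {0: "PD", 2: "TT", 4: "NPD"}


def simulate_tetrads(
    n: int,
    d1_cm: float,
    d2_cm: float,
    nd_prob: float = 0.0,
    seed=None,
) -> TetradSimulation:
    """Simulate ``n`` meioses of the three-colour tetrad assay.

    Crossover counts per interval are Poisson with mean m = 2 d / 100 per
    bivalent (a map distance of d cM means d/100 Morgans per chromatid, and
    each crossover involves half the chromatids), each crossover pairing one
    uniformly chosen chromatid of each homolog — no chromatid or crossover
    interference. With probability ``nd_prob`` a meiosis instead undergoes
    MI nondisjunction of the marked chromosome, yielding two triple-positive
    disomic spores and two dark nullisomic spores. Spore order is shuffled
    within each tetrad.
    """
    if d1_cm < 0 or d2_cm < 0 or not 0 <= nd_prob <= 1 or n < 1:
        raise ValueError("invalid simulation parameters")
    rng = _rng(seed)
    m1, m2 = 2.0 * d1_cm / 100.0, 2.0 * d2_cm / 100.0
    nd = rng.random(n) < nd_prob
    n_co1 = rng.poisson(m1, size=n)
    n_co2 = rng.poisson(m2, size=n)

    # Origin chromatid of each spore's segment at ARG4 (A) and THR1 (T);
    # chromatids 0,1 belong to homolog 1 (carrying the CEN8-RFP and
    # ARG4-GFP reporters), chromatids 2,3 to homolog 2 (THR1-BFP). A
    # crossover in interval 1 exchanges everything distal to CEN8-ARG4
    # (both loci); one in interval 2 exchanges only the THR1 segment.
    # Each chiasma joins one chromatid that is locally on the homolog-1
    # axis with one on the homolog-2 axis: distal to an earlier exchange a
    # chromatid follows the other homolog, so partners are drawn by current
    # segment origin, not by centromere.
    base = np.broadcast_to(np.arange(4), (n, 4)).copy()
    A = base.copy()
    T = base.copy()
    rows = np.arange(n)

    def _exchange(origin: np.ndarray, act: np.ndarray, swap_arrays) -> None:
        # Split strands by the homolog of their current distal content and
        # pick one of each uniformly.
        order = np.argsort(origin[act] >= 2, axis=1, kind="stable")
        i1 = order[np.arange(act.size), rng.integers(0, 2, size=act.size)]
        i2 = order[np.arange(act.size), 2 + rng.integers(0, 2, size=act.size)]
        for arr in swap_arrays:
            tmp = arr[act, i1].copy()
            arr[act, i1] = arr[act, i2]
            arr[act, i2] = tmp

    for step in range(int(n_co1.max(initial=0))):
        act = rows[(n_co1 > step) & ~nd]
        if act.size == 0:
            break
        _exchange(A, act, (A, T))
    for step in range(int(n_co2.max(initial=0))):
        act = rows[(n_co2 > step) & ~nd]
        if act.size == 0:
            break
        _exchange(T, act, (T,))

    hom1_cen8 = base < 2  # CEN8 never recombines away from its chromatid
    hom1_arg4 = A < 2
    hom1_thr1 = T < 2
    rec1 = (hom1_cen8 != hom1_arg4).sum(axis=1)
    rec2 = (hom1_arg4 != hom1_thr1).sum(axis=1)

    flags = np.stack([hom1_cen8, hom1_arg4, ~hom1_thr1], axis=2)

    # Overwrite nondisjunction meioses with the 2x(RGB) + 2x(dark) pattern.
    nd_pattern = np.array(
        [[1, 1, 1], [1, 1, 1], [0, 0, 0], [0, 0, 0]], dtype=bool
    )
    flags[nd] = nd_pattern

    # Shuffle spore order within each tetrad.
    perm = np.argsort(rng.random((n, 4)), axis=1)
    flags = np.take_along_axis(flags, perm[:, :, None], axis=1)

    interval1 = np.array([_TYPE_NAMES.get(r) for r in rec1], dtype=object)
    interval2 = np.array([_TYPE_NAMES.get(r) for r in rec2], dtype=object)
    interval1[nd] = None
    interval2[nd] = None
    n_co1 = n_co1.copy()
    n_co2 = n_co2.copy()
    n_co1[nd] = 0
    n_co2[nd] = 0
    truth = pd.DataFrame(
        {
            "nd": nd,
            "n_co1": n_co1,
            "n_co2": n_co2,
            "interval1": interval1,
            "interval2": interval2,
        }
    )
    return TetradSimulation(
        patterns=flags,
        truth=truth,
        params={"n": n, "d1_cm": d1_cm, "d2_cm": d2_cm, "nd_prob": nd_prob},
    )


# ---------------------------------------------------------------------------
# Gel lanes
# ---------------------------------------------------------------------------


def make_synthetic_protein(
    length: int = 769,
    identifier: str = "synthetic-protein",
    tag_mass_da: float = 3000.0,
    domains: dict | None = None,
    seed=None,
) -> ProteinRecord:
    """A random protein sequence with a plausible domain layout.

    Used wherever a footprinting target is needed without shipping a real
    sequence; residue composition is uniform over the 20 amino acids, which
    keeps the mean residue mass near the usual ~110 Da.
    """
    rng = _rng(seed)
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    seq = "".join(rng.choice(alphabet, size=length))
    if domains is None:
        a = int(round(length * 0.45))
        b = int(round(length * 0.65))
        domains = {
            "N-terminal": (1, a),
            "linker": (a + 1, b),
            "C-terminal": (b + 1, length),
        }
    return ProteinRecord(
        identifier=identifier, sequence=seq, tag_mass_da=tag_mass_da, domains=domains
    )


@dataclass
class LaneSimulation:
    """A simulated sample lane, its ladder lane, and the generative truth."""

    sample_lane: LaneProfile
    ladder_lane: LaneProfile
    ladder: MarkerLadder
    protein: ProteinRecord
    truth: dict

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, lane in (("sample", self.sample_lane), ("ladder", self.ladder_lane)):
            pd.DataFrame(
                {"position": lane.position, "intensity": lane.intensity}
            ).to_csv(outdir / f"lane_{name}.csv", index=False)
        with open(outdir / "ladder.json", "w") as fh:
            json.dump({"markers": [{"kda": k} for k in self.ladder.kda]}, fh)
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def simulate_lane_set(
    protein: ProteinRecord,
    sites,
    intensities=None,
    ladder_kda=DEFAULT_LADDER_KDA,
    lane_span=(10.0, 90.0),
    n_samples: int = 4000,
    band_sigma_frac: float = 0.005,
    noise_frac: float = 0.015,
    full_length_intensity: float = 1.0,
    migration_law=None,
    seed=None,
) -> LaneSimulation:
    """Forward-model a cleavage-fragment lane and its marker ladder.

    Fragment molecular weights are tag + cumulative average residue mass at
    each true site; band centres follow the log-linear migration law
    migration = a - b ln(MW), with a, b set so the ladder spans
    ``lane_span`` (in lane coordinates 0..100). Bands are Gaussians of width
    ``band_sigma_frac`` of the lane, plus the uncleaved full-length band,
    plus additive Gaussian noise of ``noise_frac`` of the tallest band. The
    default migration law is intentionally not a quartic: the quartic
    calibration must cope with a merely smooth, monotone truth. Pass a
    callable ``migration_law(mw_kda) -> lane coordinate`` to override it
    (e.g. an exact quartic for round-trip identity checks).
    """
    rng = _rng(seed)
    sites = [int(s) for s in sites]
    if any(not 1 <= s <= len(protein) for s in sites):
        raise ValueError("cleavage sites must lie within the protein")
    ladder_kda = np.sort(np.asarray(ladder_kda, dtype=float))[::-1]
    if len(ladder_kda) < 5:
        raise ValueError("need at least 5 ladder markers")
    if intensities is None:
        intensities = [1.0] * len(sites)
    if len(intensities) != len(sites):
        raise ValueError("one intensity per site required")

    lo_mig, hi_mig = lane_span
    b = (hi_mig - lo_mig) / np.log(ladder_kda.max() / ladder_kda.min())
    a = lo_mig + b * np.log(ladder_kda.max())
    if migration_law is None:
        migration = lambda mw_kda: a - b * np.log(mw_kda)
        law_desc = {"a": float(a), "b": float(b)}
    else:
        migration = migration_law
        law_desc = "custom"

    prefix = protein.prefix_masses_da()
    frag_kda = [prefix[s - 1] / 1000.0 for s in sites]
    full_kda = prefix[-1] / 1000.0

    x = np.linspace(0.0, 100.0, n_samples)
    sigma = band_sigma_frac * 100.0

    def lane(centers, heights):
        y = np.zeros_like(x)
        for c, h in zip(centers, heights):
            y += h * np.exp(-0.5 * ((x - c) / sigma) ** 2)
        if noise_frac > 0 and y.max() > 0:
            y = y + rng.normal(0.0, noise_frac * y.max(), size=x.shape)
        return LaneProfile(x, np.clip(y, 0.0, None))

    centers = [migration(k) for k in frag_kda] + [migration(full_kda)]
    heights = list(intensities) + [full_length_intensity]
    sample = lane(centers, heights)
    ladder_lane = lane([migration(k) for k in ladder_kda], [1.0] * len(ladder_kda))

    truth = {
        "sites": sites,
        "fragment_kda": frag_kda,
        "full_length_kda": full_kda,
        "band_centers": centers[:-1],
        "full_length_center": centers[-1],
        "migration_law": law_desc,
        "ladder_kda": ladder_kda.tolist(),
        "ladder_centers": [float(migration(k)) for k in ladder_kda],
    }
    ladder = MarkerLadder(kda=ladder_kda)
    return LaneSimulation(
        sample_lane=sample, ladder_lane=ladder_lane, ladder=ladder,
        protein=protein, truth=truth,
    )


# ---------------------------------------------------------------------------
# AFM fields
# ---------------------------------------------------------------------------


@dataclass
class AFMSimulation:
    heightmap: HeightMap
    truth: pd.DataFrame  # row, col, volume_nm3, sigma_nm, class

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        np.savetxt(outdir / "heightmap.txt", self.heightmap.heights, fmt="%.5f")
        with open(outdir / "heightmap.txt.json", "w") as fh:
            json.dump({"pixel_size_nm": self.heightmap.pixel_size_nm}, fh)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def simulate_afm_field(
    n_particles: int = 60,
    dimer_fraction: float = 1.0 / 3.0,
    shape: tuple[int, int] = (512, 512),
    pixel_size_nm: float = 1000.0 / 512.0,
    monomer_volume_nm3: tuple[float, float] = (110.0, 20.0),
    dimer_volume_nm3: tuple[float, float] = (250.0, 40.0),
    cap_sigma_nm: tuple[float, float] = (3.0, 5.0),
    noise_sd_nm: float = 0.08,
    seed=None,
) -> AFMSimulation:
    """Scatter Gaussian-cap particles on a flat surface with additive noise.

    Each particle is a rotationally symmetric Gaussian cap of footprint width
    sigma (drawn uniformly from ``cap_sigma_nm``) scaled so its analytic
    volume 2 pi sigma^2 h0 equals the drawn true volume. Volumes come from a
    monomer/dimer normal mixture (``(mean, sd)`` pairs, clipped to stay
    within the matching classification window so generative classes are
    unambiguous). Particles are placed by rejection sampling with a minimum
    separation and an edge margin; an infeasible density raises an error.
    """
    if noise_sd_nm < 0:
        raise ValueError("noise SD must be non-negative")
    rng = _rng(seed)
    nrow, ncol = shape
    heights = np.zeros(shape)
    sig_lo, sig_hi = cap_sigma_nm

    is_dimer = rng.random(n_particles) < dimer_fraction
    volumes = np.where(
        is_dimer,
        np.clip(
            rng.normal(dimer_volume_nm3[0], dimer_volume_nm3[1], n_particles),
            175.0, 345.0,
        ),
        np.clip(
            rng.normal(monomer_volume_nm3[0], monomer_volume_nm3[1], n_particles),
            45.0, 165.0,
        ),
    )
    sigmas = rng.uniform(sig_lo, sig_hi, n_particles)

    margin_px = int(np.ceil(6.0 * sig_hi / pixel_size_nm))
    min_sep_px = 2 * margin_px
    if nrow - 2 * margin_px <= 0 or ncol - 2 * margin_px <= 0:
        raise ValueError("field too small for the requested particle size")
    centers: list[tuple[float, float]] = []
    max_tries = 200 * n_particles
    tries = 0
    while len(centers) < n_particles:
        tries += 1
        if tries > max_tries:
            raise ValueError("particle density infeasible for non-overlapping placement")
        r = rng.uniform(margin_px, nrow - margin_px)
        c = rng.uniform(margin_px, ncol - margin_px)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep_px**2 for r0, c0 in centers):
            centers.append((r, c))

    rows_idx, cols_idx = np.indices(shape)
    records = []
    for (r, c), vol, sig in zip(centers, volumes, sigmas):
        h0 = vol / (2.0 * np.pi * sig**2)
        sig_px = sig / pixel_size_nm
        d2 = (rows_idx - r) ** 2 + (cols_idx - c) ** 2
        heights += h0 * np.exp(-0.5 * d2 / sig_px**2)
        records.append(
            {
                "row": r,
                "col": c,
                "volume_nm3": vol,
                "sigma_nm": sig,
                "class": classify_volume(vol),
            }
        )
    if noise_sd_nm > 0:
        heights = heights + rng.normal(0.0, noise_sd_nm, size=shape)
    return AFMSimulation(
        heightmap=HeightMap(heights, pixel_size_nm),
        truth=pd.DataFrame(records),
    )


# ---------------------------------------------------------------------------
# Titrations and reversion assays
# ---------------------------------------------------------------------------


@dataclass
class TitrationSimulation:
    series: TitrationSeries
    truth: dict


#: Default titration grids: protein (nM) for binding, ATP (mM) for kinetics.
#: The binding grid is a two-fold-style dilution series concentrated around
#: the tens-of-nM half-saturation range of the binding assays, the design an
#: EMSA titration would actually use.
HILL_DEFAULT_X_NM = (12.5, 25.0, 37.5, 50.0, 75.0, 100.0, 150.0, 200.0, 300.0, 400.0)
MM_DEFAULT_X_MM = (0.01, 0.02, 0.04, 0.08, 0.16, 0.32, 0.64, 1.28)


def simulate_titration(
    model: str,
    params: dict,
    x=None,
    noise_sd: float = 0.03,
    kind: str | None = None,
    seed=None,
) -> TitrationSimulation:
    """Exact model curve plus i.i.d. Gaussian noise.

    ``model="hill"`` needs ``params={"kd": ..., "n": ...}`` and produces an
    unbound-fraction series (noise truncated to [0, 1]); ``model="mm"``
    needs ``params={"vmax": ..., "km": ...}`` and produces rates, with
    ``noise_sd`` interpreted as a fraction of V_max.
    """
    if noise_sd < 0:
        raise ValueError("noise SD must be non-negative")
    rng = _rng(seed)
    if model == "hill":
        x = np.asarray(HILL_DEFAULT_X_NM if x is None else x, dtype=float)
        clean = 1.0 - hill_bound(x, params["kd"], params["n"])
        y = np.clip(clean + rng.normal(0.0, noise_sd, size=x.shape), 0.0, 1.0)
        series = TitrationSeries(x, y, kind=kind or "unbound_fraction")
    elif model == "mm":
        x = np.asarray(MM_DEFAULT_X_MM if x is None else x, dtype=float)
        clean = michaelis_menten(x, params["vmax"], params["km"])
        y = clean + rng.normal(0.0, noise_sd * params["vmax"], size=x.shape)
        y = np.clip(y, 0.0, None)
        series = TitrationSeries(x, y, kind=kind or "rate")
    else:
        raise ValueError(f"unknown model {model!r}")
    if len(x) < 4:
        raise ValueError("need at least 4 titration points")
    return TitrationSimulation(
        series=series,
        truth={"model": model, "params": dict(params), "noise_sd": noise_sd},
    )


def simulate_reversion_assay(
    true_frequency: float,
    cfu_per_culture: float = 1e6,
    n_cultures: int = 6,
    seed=None,
) -> pd.DataFrame:
    """Poisson revertant counts for independent cultures.

    Each culture of ``cfu_per_culture`` cells yields a Poisson number of
    revertants with mean frequency x cfu. (Jackpot-prone mutation-rate
    fluctuation is deliberately not modelled: the estimand is a frequency.)
    """
    if not 0.0 <= true_frequency <= 1.0:
        raise ValueError("frequency must be in [0, 1]")
    if cfu_per_culture <= 0 or n_cultures < 1:
        raise ValueError("need positive cfu and at least one culture")
    rng = _rng(seed)
    revertants = rng.poisson(true_frequency * cfu_per_culture, size=n_cultures)
    return pd.DataFrame(
        {"revertants": revertants, "cfu": float(cfu_per_culture)}
    )
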