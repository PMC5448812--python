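"""Hydroxyl-radical footprint mapping from gel lane traces to residue coordinates.

A tethered hydroxyl-radical source on the DNA (FeBABE) cleaves the protein
backbone near the protein-DNA interface. Because the detected fragments carry
an N-terminal epitope tag, each western-blot band is an N-terminal prefix of
the protein, and its apparent molecular weight locates the cleavage site.

The pipeline is:

1. :func:`detect_lane_peaks` -- baseline-subtract and smooth a 1-D lane
   intensity trace and find band centres with sub-sample precision;
2. :func:`fit_migration_calibration` -- fit a fourth-order polynomial of
   migration distance as a function of molecular weight to a marker ladder,
   with a monotonicity guard over the marker range;
3. :func:`estimate_cleavage_sites` -- invert the calibration numerically to
   get each fragment's molecular weight and convert it to a residue index by
   matching against the cumulative average-mass profile of the sequence;
4. :func:`domain_intensity_ratio` and :func:`select_candidate_residues` --
   summarise sites by protein domain and propose nearby basic residues
   (lysine/arginine) as candidate DNA contacts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.optimize
import scipy.signal
from Bio import SeqIO
from Bio.Data.IUPACData import protein_weights

__all__ = [
    "WATER_MASS_DA",
    "LaneProfile",
    "MarkerLadder",
    "CalibrationModel",
    "ProteinRecord",
    "CleavageSite",
    "DomainRatio",
    "detect_lane_peaks",
    "assign_ladder_peaks",
    "fit_migration_calibration",
    "estimate_cleavage_sites",
    "domain_intensity_ratio",
    "select_candidate_residues",
    "sites_to_tsv",
    "sites_to_bed",
]

WATER_MASS_DA = 18.0153

#: Average residue masses (free amino acid minus one water), Da.
RESIDUE_MASSES_DA = {
    aa: weight - WATER_MASS_DA for aa, weight in protein_weights.items()
}


@dataclass
class LaneProfile:
    """A 1-D densitometry trace of one gel lane."""

    position: np.ndarray  # migration coordinate (mm or px), strictly increasing
    intensity: np.ndarray  # arbitrary units, >= 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.position.shape != self.intensity.shape or self.position.ndim != 1:
            raise ValueError("position and intensity must be matching 1-D arrays")
        if not np.all(np.diff(self.position) > 0):
            raise ValueError("migration coordinate must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")

    @classmethod
    def from_csv(cls, path, **meta) -> "LaneProfile":
        df = pd.read_csv(path)
        pos, inten = df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy()
        return cls(pos, inten, meta=meta)

    @property
    def length(self) -> float:
        return float(self.position[-1] - self.position[0])


@dataclass
class MarkerLadder:
    """Molecular-weight standards and their detected migration positions."""

    kda: np.ndarray  # strictly decreasing with increasing migration
    labels: tuple[str, ...] | None = None
    positions: np.ndarray | None = None

    def __post_init__(self):
        self.kda = np.asarray(self.kda, dtype=float)
        if self.positions is not None:
            self.positions = np.asarray(self.positions, dtype=float)
            if self.positions.shape != self.kda.shape:
                raise ValueError("positions must match marker count")
            order = np.argsort(self.positions)
            if not np.all(np.diff(self.kda[order]) < 0):
                raise ValueError("marker MW must decrease with increasing migration")

    @classmethod
    def from_json(cls, path) -> "MarkerLadder":
        with open(path) as fh:
            payload = json.load(fh)
        kda = np.array([m["kda"] for m in payload["markers"]], dtype=float)
        labels = tuple(str(m.get("label", m["kda"])) for m in payload["markers"])
        return cls(kda=kda, labels=labels)


@dataclass
class CalibrationModel:
    """Quartic law migration = P(MW) fitted to a marker ladder.

    The polynomial is fitted in the plain power basis on molecular weight in
    kDa (not log MW). A quartic is flexible enough to follow the curvature of
    electrophoretic migration but can oscillate outside the marker range, so
    the model stores its valid MW range, enforces strict monotonicity over
    it, and inverts numerically by bisection.
    """

    coeffs: np.ndarray  # power-basis coefficients, ascending degree, len 5
    mw_range: tuple[float, float]  # kDa
    residual_rms: float

    def __post_init__(self):
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        if self.coeffs.shape != (5,):
            raise ValueError("calibration must be a degree-4 polynomial")

    def migration(self, mw_kda):
        return np.polynomial.polynomial.polyval(mw_kda, self.coeffs)

    def slope(self, mw_kda):
        """d(migration)/d(MW) in migration units per kDa."""
        dcoef = np.polynomial.polynomial.polyder(self.coeffs)
        return np.polynomial.polynomial.polyval(mw_kda, dcoef)

    @property
    def migration_range(self) -> tuple[float, float]:
        lo, hi = self.mw_range
        ends = sorted((float(self.migration(lo)), float(self.migration(hi))))
        return ends[0], ends[1]

    def mw_at(self, migration: float) -> float:
        """Invert the calibration: molecular weight (kDa) at a migration."""
        lo, hi = self.mw_range
        m_lo, m_hi = self.migration_range
        if not (m_lo <= migration <= m_hi):
            raise ValueError("migration outside the calibrated range")
        f = lambda mw: float(self.migration(mw)) - migration
        return float(scipy.optimize.brentq(f, lo, hi, xtol=1e-9))


@dataclass
class ProteinRecord:
    """A protein sequence with its tag mass and domain architecture."""

    identifier: str
    sequence: str
    tag_mass_da: float = 0.0
    domains: dict[str, tuple[int, int]] = field(default_factory=dict)

    def __post_init__(self):
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError("sequence must be non-empty")
        bad = set(self.sequence) - set(RESIDUE_MASSES_DA)
        if bad:
            raise ValueError(f"unknown residues in sequence: {sorted(bad)}")
        if self.domains:
            spans = sorted(self.domains.values())
            tiled = spans[0][0] == 1 and spans[-1][1] == len(self.sequence)
            for (a, b), (c, d) in zip(spans, spans[1:]):
                tiled &= c == b + 1
            if not tiled:
                raise ValueError("domains must tile [1, length] without overlap")

    @classmethod
    def from_fasta(cls, fasta_path, domains=None, tag_mass_da: float = 0.0) -> "ProteinRecord":
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
        if isinstance(domains, (str,)) or hasattr(domains, "read_text"):
            with open(domains) as fh:
                domains = json.load(fh)
        domains = {k: tuple(v) for k, v in (domains or {}).items()}
        return cls(
            identifier=record.id,
            sequence=str(record.seq),
            tag_mass_da=tag_mass_da,
            domains=domains,
        )

    def __len__(self) -> int:
        return len(self.sequence)

    def prefix_masses_da(self) -> np.ndarray:
        """Mass (Da) of the tagged N-terminal fragment 1..k for each k.

        A fragment of k residues weighs the sum of its residue masses plus
        one water plus the N-terminal tag.
        """
        residues = np.array([RESIDUE_MASSES_DA[aa] for aa in self.sequence])
        return np.cumsum(residues) + WATER_MASS_DA + self.tag_mass_da

    def domain_of(self, residue: int) -> str | None:
        for name, (start, end) in self.domains.items():
            if start <= residue <= end:
                return name
        return None


@dataclass(frozen=True)
class CleavageSite:
    """An inferred hydroxyl-radical cleavage position."""

    fragment_kda: float | None
    residue: int | None
    intensity: float
    uncertainty_residues: float | None
    domain: str | None = None
    migration: float | None = None
    out_of_range: bool = False


def detect_lane_peaks(
    profile: LaneProfile,
    smooth_frac: float = 0.01,
    prominence_frac: float = 0.05,
    baseline_frac: float = 0.15,
) -> list[tuple[float, float]]:
    """Detect band centres in a lane trace with sub-sample precision.

    The trace is baseline-subtracted by morphological opening (structuring
    window ``baseline_frac`` of the trace length), smoothed by a
    Savitzky-Golay filter of window ``smooth_frac`` of the trace length, and
    searched for local maxima whose prominence exceeds ``prominence_frac``
    of the tallest smoothed signal. Each peak position is refined by a local
    quadratic fit through the three samples around the maximum. A flat or
    empty trace yields no peaks.
    """
    if min(smooth_frac, prominence_frac, baseline_frac) <= 0:
        raise ValueError("settings must be positive")
    n = len(profile.intensity)
    if n < 50:
        raise ValueError("need at least 50 samples in the trace")
    y = profile.intensity.astype(float)
    base_w = max(3, int(round(baseline_frac * n)))
    baseline = scipy.ndimage.grey_opening(y, size=base_w)
    y = y - baseline
    win = max(5, int(round(smooth_frac * n)) | 1)  # odd
    smooth = scipy.signal.savgol_filter(y, window_length=win, polyorder=2)
    top = float(smooth.max(initial=0.0))
    if top <= 0:
        return []
    idx, _ = scipy.signal.find_peaks(smooth, prominence=prominence_frac * top)
    x = profile.position
    dx = np.diff(x).mean()
    peaks = []
    for i in idx:
        if 0 < i < n - 1:
            ym, y0, yp = smooth[i - 1], smooth[i], smooth[i + 1]
            denom = ym - 2 * y0 + yp
            delta = 0.5 * (ym - yp) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
            pos = float(x[i] + delta * dx)
            height = float(y0 - 0.25 * (ym - yp) * delta)
        else:
            pos, height = float(x[i]), float(smooth[i])
        peaks.append((pos, height))
    return peaks


def assign_ladder_peaks(ladder: MarkerLadder, peaks) -> MarkerLadder:
    """Pair detected ladder-lane peaks with marker molecular weights.

    The ``len(ladder.kda)`` most intense peaks are kept and matched, in order
    of increasing migration, to the markers in order of decreasing MW.
    """
    k = len(ladder.kda)
    if len(peaks) < k:
        raise ValueError(f"found {len(peaks)} peaks for {k} markers")
    best = sorted(peaks, key=lambda p: p[1], reverse=True)[:k]
    positions = np.sort([p[0] for p in best])
    kda = np.sort(ladder.kda)[::-1]
    return MarkerLadder(kda=kda, labels=ladder.labels, positions=positions)


def fit_migration_calibration(ladder: MarkerLadder) -> CalibrationModel:
    """Least-squares quartic of migration distance on molecular weight.

    Requires at least 5 markers with detected positions, and rejects fits
    that are not strictly monotone over the marker MW range (a non-monotone
    quartic cannot be inverted to recover fragment weights).
    """
    if ladder.positions is None:
        raise ValueError("ladder has no detected migration positions")
    if len(ladder.kda) < 5:
        raise ValueError("need at least 5 markers for a quartic fit")
    mw, mig = ladder.kda, ladder.positions
    coeffs = np.polynomial.polynomial.polyfit(mw, mig, deg=4)
    fitted = np.polynomial.polynomial.polyval(mw, coeffs)
    rms = float(np.sqrt(np.mean((fitted - mig) ** 2)))
    model = CalibrationModel(
        coeffs=coeffs, mw_range=(float(mw.min()), float(mw.max())), residual_rms=rms
    )
    grid = np.linspace(*model.mw_range, 512)
    sign = np.sign(model.slope(grid))
    if np.any(sign == 0) or len(np.unique(sign)) > 1:
        raise ValueError(
            "calibration fit is not monotone over the marker range; "
            "check ladder assignment or use more markers"
        )
    return model


def estimate_cleavage_sites(
    peaks,
    calibration: CalibrationModel,
    protein: ProteinRecord,
    min_uncertainty_residues: float = 5.0,
) -> list[CleavageSite]:
    """Convert band peaks to cleavage positions in residue coordinates.

    Each peak's migration is inverted through the calibration to a fragment
    molecular weight; the residue index k minimising |fragment mass - mass of
    the tagged prefix 1..k| (average residue masses) is the estimated
    cleavage site. The per-site uncertainty propagates the calibration
    residual RMS through the local slope of the migration law, floored at
    ``min_uncertainty_residues`` (the assay does not resolve finer than a few
    residues regardless of fit quality). Peaks outside the calibrated
    migration range are flagged and carry no residue assignment.
    """
    prefix = protein.prefix_masses_da()
    mean_res_kda = float(np.mean(np.diff(prefix))) / 1000.0 if len(prefix) > 1 else 0.11
    m_lo, m_hi = calibration.migration_range
    sites = []
    for pos, intensity in peaks:
        if not (m_lo <= pos <= m_hi):
            sites.append(
                CleavageSite(
                    fragment_kda=None, residue=None, intensity=float(intensity),
                    uncertainty_residues=None, migration=float(pos), out_of_range=True,
                )
            )
            continue
        mw_kda = calibration.mw_at(pos)
        residue = int(np.argmin(np.abs(prefix - mw_kda * 1000.0))) + 1
        slope_per_residue = abs(calibration.slope(mw_kda)) * mean_res_kda
        if slope_per_residue > 0:
            unc = calibration.residual_rms / slope_per_residue
        else:
            unc = float("inf")
        unc = max(float(unc), min_uncertainty_residues)
        sites.append(
            CleavageSite(
                fragment_kda=mw_kda,
                residue=residue,
                intensity=float(intensity),
                uncertainty_residues=unc,
                domain=protein.domain_of(residue),
                migration=float(pos),
            )
        )
    return sites


@dataclass(frozen=True)
class DomainRatio:
    """Ratio of summed cleavage intensities between two domains."""

    value: float
    numerator_intensity: float
    denominator_intensity: float
    infinite: bool = False


def domain_intensity_ratio(
    sites,
    protein: ProteinRecord,
    numerator: str = "N-terminal",
    denominator: str = "linker",
) -> DomainRatio:
    """Summed cleavage intensity in one domain over another.

    The headline use is the N-terminal-domain / linker intensity ratio, which
    summarises how cleavage (hence DNA proximity) redistributes between
    substrates. Sites in other domains, unassigned sites, and out-of-range
    peaks are ignored. A zero denominator yields an infinite ratio, flagged.
    """
    sums = {numerator: 0.0, denominator: 0.0}
    seen = False
    for s in sites:
        if s.residue is None:
            continue
        dom = s.domain if s.domain is not None else protein.domain_of(s.residue)
        if dom in sums:
            sums[dom] += s.intensity
            seen = True
    if not seen:
        raise ValueError("no sites in either domain")
    num, den = sums[numerator], sums[denominator]
    if den == 0:
        return DomainRatio(float("inf"), num, den, infinite=True)
    return DomainRatio(num / den, num, den)


def select_candidate_residues(
    protein: ProteinRecord,
    site: int,
    window: int = 12,
    alignment=None,
    min_conservation: float = 0.7,
) -> set[int]:
    """Basic residues (K/R) within ``window`` residues of a cleavage site.

    Hydroxyl-radical cleavage marks backbone proximity to the DNA, so the
    actual contacts are sought among nearby positively charged residues. If
    ``alignment`` (a list of ``(identifier, aligned_sequence)`` pairs, one of
    which matches ``protein.identifier``) is given, candidates are filtered
    to alignment columns in which at least ``min_conservation`` of the
    sequences carry K or R.
    """
    if not 1 <= site <= len(protein):
        raise ValueError("site outside the protein sequence")
    if window <= 0:
        raise ValueError("window must be positive")
    lo = max(1, site - window)
    hi = min(len(protein), site + window)
    candidates = {
        i for i in range(lo, hi + 1) if protein.sequence[i - 1] in "KR"
    }
    if alignment is None or not candidates:
        return candidates
    rows = dict(alignment)
    if protein.identifier not in rows:
        raise ValueError("alignment does not contain the protein's row")
    ref = rows[protein.identifier].upper()
    # residue index -> alignment column for the reference row
    col_of = {}
    res = 0
    for col, ch in enumerate(ref):
        if ch != "-":
            res += 1
            col_of[res] = col
    kept = set()
    seqs = [s.upper() for s in rows.values()]
    for residue in candidates:
        col = col_of.get(residue)
        if col is None:
            continue
        frac = np.mean([s[col] in "KR" for s in seqs])
        if frac >= min_conservation:
            kept.add(residue)
    return kept


def load_alignment_fasta(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA into (identifier, aligned sequence) pairs,
    the format :func:`select_candidate_residues` accepts."""
    from Bio import AlignIO

    aln = AlignIO.read(str(path), "fasta")
    return [(rec.id, str(rec.seq)) for rec in aln]


def sites_to_tsv(sites, path) -> None:
    pd.DataFrame(
        [
            {
                "fragment_kda": s.fragment_kda,
                "residue": s.residue,
                "uncertainty_residues": s.uncertainty_residues,
                "intensity": s.intensity,
                "domain": s.domain,
                "out_of_range": s.out_of_range,
            }
            for s in sites
        ]
    ).to_csv(path, sep="\t", index=False)


def sites_to_bed(sites, protein: ProteinRecord, path) -> None:
    """Write sites as BED-like residue intervals (site +/- uncertainty)."""
    with open(path, "w") as fh:
        for s in sites:
            if s.residue is None:
                continue
            half = int(round(s.uncertainty_residues or 0))
            start = max(0, s.residue - 1 - half)  # BED is 0-based half-open
            end = min(len(protein), s.residue + half)
            fh.write(
                f"{protein.identifier}\t{start}\t{end}\tsite_{s.residue}\t{s.intensity:.4g}\n"
            )
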