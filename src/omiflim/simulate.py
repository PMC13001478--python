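"""Synthetic FLIM scenes and feature tables with known ground truth.

Two generation paths are provided:

* the *imaging* path (:func:`build_scene`) renders multi-cell fields of view
  as per-pixel photon-arrival histograms for two spectral channels
  (NAD(P)H-like and FAD-like), Poisson-sampled from biexponential emitters
  convolved with a Gaussian instrument response — the full observable the
  decay-fitting stage consumes;
* the *statistical* path (:func:`sample_feature_table`) draws per-cell OMI
  variables directly from the cell-type profiles, bypassing photon physics,
  for fast tests of the downstream statistics and classifiers.

Cell-type profiles parameterize both paths.  The default PBMC profiles place
monocytes at low NAD(P)H mean lifetime, high NAD(P)H alpha1 and large area
relative to lymphocytes, and give B cells a slightly elevated alpha1 — the
direction of the contrasts this kind of autofluorescence imaging resolves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import BIN_WIDTH_PS, N_BINS, DecayModel, bin_centers

#: Canonical order of the 10 OMI variables used throughout the package.
OMI_VARIABLES = [
    "nadph_tau_m",
    "nadph_tau1",
    "nadph_tau2",
    "nadph_alpha1",
    "fad_tau_m",
    "fad_tau1",
    "fad_tau2",
    "fad_alpha1",
    "orr",
    "area_px",
]

CHANNELS = ("nadph", "fad")


@dataclass(frozen=True)
class EmitterSpec:
    """Ground-truth biexponential emitter for one pixel and one channel.

    ``alpha1_frac`` is the fraction of emitted photons in the short (tau1)
    component; the decay shape is normalized to unit area before scaling by
    ``photons_per_pixel``, so amplitudes and photon fractions coincide.
    """

    tau1: float  # ps, short (quenched) component
    tau2: float  # ps, long (unquenched) component
    alpha1_frac: float  # photon fraction of the short component, in [0, 1]
    photons_per_pixel: float  # expected total decay photons (Poisson mean)
    background_rate: float = 0.0  # expected photons per bin from constant C

    def __post_init__(self):
        if not 0 < self.tau1 <= self.tau2:
            raise ValueError(f"need 0 < tau1 <= tau2, got {self.tau1}, {self.tau2}")
        if not 0 <= self.alpha1_frac <= 1:
            raise ValueError(f"alpha1_frac must be in [0, 1], got {self.alpha1_frac}")
        if self.photons_per_pixel <= 0:
            raise ValueError("photons_per_pixel must be positive")
        if self.background_rate < 0:
            raise ValueError("background_rate must be nonnegative")

    @property
    def tau_m(self) -> float:
        """Amplitude-weighted mean lifetime (ps)."""
        return self.alpha1_frac * self.tau1 + (1 - self.alpha1_frac) * self.tau2


#: (mean, coefficient of variation) pair describing a between-cell spread.
Dist = tuple[float, float]


@dataclass(frozen=True)
class ChannelDist:
    """Between-cell distributions of emitter parameters for one channel."""

    tau1: Dist
    tau2: Dist
    alpha1_frac: Dist
    photons_per_pixel: Dist
    background_rate: float = 0.0

    def draw(self, rng: np.random.Generator) -> EmitterSpec:
        def _draw(d: Dist, lo: float, hi: float | None) -> float:
            mean, cv = d
            if cv < 0:
                raise ValueError("coefficient of variation must be >= 0")
            x = rng.normal(mean, cv * mean) if cv > 0 else mean
            return float(np.clip(x, lo, hi))

        t1 = _draw(self.tau1, 1.0, None)
        t2 = _draw(self.tau2, 1.0, None)
        if t1 > t2:
            t1, t2 = t2, t1
        return EmitterSpec(
            tau1=t1,
            tau2=t2,
            alpha1_frac=_draw(self.alpha1_frac, 0.0, 1.0),
            photons_per_pixel=_draw(self.photons_per_pixel, 1.0, None),
            background_rate=self.background_rate,
        )


@dataclass(frozen=True)
class CellTypeProfile:
    """One cell type's parameter distributions and abundance in a field."""

    name: str
    nadph: ChannelDist
    fad: ChannelDist
    area_px: Dist
    abundance: float = 1.0

    def channel(self, name: str) -> ChannelDist:
        if name not in CHANNELS:
            raise ValueError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass
class SyntheticScene:
    """A ground-truthed field of view: labels, truth table, decay cubes, IRFs."""

    label_image: np.ndarray  # int, 0 = background
    truth_table: pd.DataFrame  # one row per label
    cubes: dict  # channel name -> (H, W, T) int photon counts
    irfs: dict  # channel name -> 1-D unit-sum histogram
    bin_width: float
    rng_seed: int


def make_irf(
    fwhm: float,
    center: float,
    n_bins: int = N_BINS,
    bin_width: float = BIN_WIDTH_PS,
) -> np.ndarray:
    """Gaussian instrument response, unit area, on the TCSPC time axis.

    Emulates the temporal response measured from second-harmonic generation
    of a urea crystal.  ``fwhm`` and ``center`` are in picoseconds.
    """
    if fwhm <= 0:
        raise ValueError("fwhm must be positive")
    if n_bins < 16:
        raise ValueError("need at least 16 bins")
    window = n_bins * bin_width
    if not 0 <= center <= window:
        raise ValueError(f"IRF center {center} ps outside time window [0, {window}] ps")
    t = bin_centers(n_bins, bin_width)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    irf = np.exp(-0.5 * ((t - center) / sigma) ** 2)
    s = irf.sum()
    if s == 0:  # pathologically narrow: delta at the center bin
        irf = np.zeros(n_bins)
        irf[min(int(center / bin_width), n_bins - 1)] = 1.0
        return irf
    return irf / s


def expected_decay(
    spec: EmitterSpec,
    irf: np.ndarray,
    bin_width: float = BIN_WIDTH_PS,
) -> np.ndarray:
    """Expected (noise-free) counts per bin for an emitter."""
    m = DecayModel(irf, bin_width)
    a1 = spec.photons_per_pixel * spec.alpha1_frac
    a2 = spec.photons_per_pixel * (1 - spec.alpha1_frac)
    return m.expected(spec.tau1, spec.tau2, a1, a2, spec.background_rate)


def simulate_decay(
    spec: EmitterSpec,
    irf: np.ndarray,
    rng_seed: int | np.random.Generator,
    bin_width: float = BIN_WIDTH_PS,
) -> np.ndarray:
    """Poisson-sample one photon-arrival histogram from an emitter."""
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    return rng.poisson(expected_decay(spec, irf, bin_width)).astype(np.int64)


# ---------------------------------------------------------------------------
# Scene construction
# ---------------------------------------------------------------------------


def _rasterize_ellipse(
    center: tuple[float, float],
    area: float,
    aspect: float,
    theta_cos_sin: tuple[float, float],
    shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of an area-preserving rotated ellipse footprint."""
    r = np.sqrt(area / np.pi)
    a, b = r * np.sqrt(aspect), r / np.sqrt(aspect)
    cr, cc = center
    cth, sth = theta_cos_sin
    half = int(np.ceil(max(a, b))) + 1
    rr, cc_idx = np.meshgrid(
        np.arange(int(cr) - half, int(cr) + half + 1),
        np.arange(int(cc) - half, int(cc) + half + 1),
        indexing="ij",
    )
    dr, dc = rr - cr, cc_idx - cc
    u = cth * dr + sth * dc
    v = -sth * dr + cth * dc
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    rows, cols = rr[inside], cc_idx[inside]
    ok = (rows >= 0) & (rows < shape[0]) & (cols >= 0) & (cols < shape[1])
    return rows[ok], cols[ok]


def build_scene(
    profiles: list[CellTypeProfile],
    field_size: tuple[int, int] = (512, 512),
    n_cells: int = 100,
    rng_seed: int = 0,
    irf_fwhm: float = 220.0,
    irf_center: float = 1000.0,
    n_bins: int = N_BINS,
    bin_width: float = BIN_WIDTH_PS,
    background_rate: float = 0.0,
    max_retries: int = 500,
) -> SyntheticScene:
    """Render a multi-cell field of view with per-pixel decay histograms.

    Cells are axis-jittered ellipses placed by rejection sampling so that
    footprints never overlap.  Each cell draws its true emitter parameters
    (per channel) and area from its type's profile; background pixels carry
    only ``background_rate`` photons per bin.  Decay photon streams are keyed
    by (seed, channel, cell id) so any cell can be regenerated independently.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    abund = np.array([p.abundance for p in profiles], dtype=float)
    if abs(abund.sum() - 1.0) > 1e-6:
        raise ValueError(f"profile abundances must sum to 1, got {abund.sum()}")

    h, w = field_size
    rng = np.random.default_rng([rng_seed, 0])
    label_image = np.zeros((h, w), dtype=np.int32)
    type_idx = rng.choice(len(profiles), size=n_cells, p=abund)

    rows_of: list[tuple[np.ndarray, np.ndarray]] = []
    truth_rows = []
    for cid, ti in enumerate(type_idx, start=1):
        prof = profiles[ti]
        placed = False
        for _ in range(max_retries):
            mean_a, cv_a = prof.area_px
            area = max(6.0, rng.normal(mean_a, cv_a * mean_a) if cv_a > 0 else mean_a)
            aspect = rng.uniform(0.6, 1.0 / 0.6)
            ang = rng.uniform(0, np.pi)
            margin = np.sqrt(area / np.pi) / 0.6 + 2
            center = (rng.uniform(margin, h - margin), rng.uniform(margin, w - margin))
            rr, cc = _rasterize_ellipse(
                center, area, aspect, (np.cos(ang), np.sin(ang)), (h, w)
            )
            if len(rr) == 0 or np.any(label_image[rr, cc] != 0):
                continue
            label_image[rr, cc] = cid
            rows_of.append((rr, cc))
            placed = True
            break
        if not placed:
            density = (label_image > 0).mean()
            raise RuntimeError(
                f"could not place cell {cid} after {max_retries} tries; "
                f"achieved density {density:.1%} with {cid - 1} cells"
            )
        specs = {ch: prof.channel(ch).draw(rng) for ch in CHANNELS}
        row = {
            "cell_id": cid,
            "cell_type": prof.name,
            "area_px": len(rows_of[-1][0]),
            "small": len(rows_of[-1][0]) < 70,
        }
        for ch in CHANNELS:
            s = specs[ch]
            row.update(
                {
                    f"{ch}_tau1": s.tau1,
                    f"{ch}_tau2": s.tau2,
                    f"{ch}_alpha1_frac": s.alpha1_frac,
                    f"{ch}_photons": s.photons_per_pixel,
                    f"{ch}_tau_m": s.tau_m,
                }
            )
        truth_rows.append(row)

    truth = pd.DataFrame(truth_rows)
    irfs = {ch: make_irf(irf_fwhm, irf_center, n_bins, bin_width) for ch in CHANNELS}
    cubes = {}
    for ci, ch in enumerate(CHANNELS):
        cube = np.zeros((h, w, n_bins), dtype=np.int32)
        if background_rate > 0:
            bg_rng = np.random.default_rng([rng_seed, 1 + ci])
            cube += bg_rng.poisson(background_rate, size=(h, w, n_bins)).astype(np.int32)
        for (rr, cc), row in zip(rows_of, truth.itertuples()):
            spec = EmitterSpec(
                tau1=getattr(row, f"{ch}_tau1"),
                tau2=getattr(row, f"{ch}_tau2"),
                alpha1_frac=getattr(row, f"{ch}_alpha1_frac"),
                photons_per_pixel=getattr(row, f"{ch}_photons"),
                background_rate=background_rate,
            )
            lam = expected_decay(spec, irfs[ch], bin_width) - background_rate
            cell_rng = np.random.default_rng([rng_seed, 10 + ci, int(row.cell_id)])
            cube[rr, cc, :] += cell_rng.poisson(
                np.clip(lam, 0, None), size=(len(rr), n_bins)
            ).astype(np.int32)
        cubes[ch] = cube

    return SyntheticScene(
        label_image=label_image,
        truth_table=truth,
        cubes=cubes,
        irfs=irfs,
        bin_width=bin_width,
        rng_seed=rng_seed,
    )


# ---------------------------------------------------------------------------
# Statistical (feature-table) path
# ---------------------------------------------------------------------------


def sample_feature_table(
    profiles: list[CellTypeProfile],
    n_per_type: int,
    rng_seed: int = 0,
    donor: str = "sim",
    condition: str = "quiescent",
) -> pd.DataFrame:
    """Draw a per-cell OMI feature table directly from cell-type profiles.

    Bypasses photon physics: each cell's lifetime parameters, intensities and
    area are drawn from the profile distributions and combined into the 10
    OMI variables, which makes the statistical and classification stages
    testable at large n in milliseconds.
    """
    if n_per_type < 1:
        raise ValueError("n_per_type must be >= 1")
    rng = np.random.default_rng(rng_seed)
    rows = []
    cid = 0
    for prof in profiles:
        for _ in range(n_per_type):
            cid += 1
            mean_a, cv_a = prof.area_px
            area = max(
                1.0, rng.normal(mean_a, cv_a * mean_a) if cv_a > 0 else mean_a
            )
            row = {
                "cell_id": cid,
                "donor": donor,
                "condition": condition,
                "cell_type": prof.name,
                "area_px": float(np.round(area)),
            }
            intens = {}
            for ch in CHANNELS:
                s = prof.channel(ch).draw(rng)
                row[f"{ch}_tau1"] = s.tau1
                row[f"{ch}_tau2"] = s.tau2
                row[f"{ch}_tau_m"] = s.tau_m
                row[f"{ch}_alpha1"] = 100.0 * s.alpha1_frac
                intens[ch] = s.photons_per_pixel
            row["orr"] = intens["nadph"] / (intens["nadph"] + intens["fad"])
            row["mean_nadph_intensity"] = intens["nadph"]
            row["chi2_mean"] = 1.0
            row["chi2_max"] = 1.0
            rows.append(row)
    cols = ["cell_id", "donor", "condition", "cell_type"] + OMI_VARIABLES + [
        "mean_nadph_intensity",
        "chi2_mean",
        "chi2_max",
    ]
    return pd.DataFrame(rows)[cols]


# ---------------------------------------------------------------------------
# Default PBMC-like profiles
# ---------------------------------------------------------------------------


def _chan(tau1, tau2, alpha1, photons, cv=0.05, photons_cv=0.10) -> ChannelDist:
    return ChannelDist(
        tau1=(tau1, cv),
        tau2=(tau2, cv),
        alpha1_frac=(alpha1, cv),
        photons_per_pixel=(photons, photons_cv),
    )


def default_profiles() -> list[CellTypeProfile]:
    """Five PBMC-like cell types with the qualitative contrasts of interest.

    Monocytes: low NAD(P)H tau_m (via high alpha1), large area.  B cells:
    slightly elevated NAD(P)H alpha1.  NK cells: shifted FAD kinetics and
    redox ratio.  Values are literature-typical NAD(P)H/FAD biexponential
    parameters; absolute numbers are illustrative, contrasts directional.
    """
    return [
        CellTypeProfile(
            "helper_t",
            nadph=_chan(400, 2600, 0.72, 120),
            fad=_chan(350, 2300, 0.72, 100),
            area_px=(95, 0.18),
            abundance=0.30,
        ),
        CellTypeProfile(
            "cytotoxic_t",
            nadph=_chan(405, 2620, 0.72, 120),
            fad=_chan(355, 2310, 0.72, 100),
            area_px=(95, 0.18),
            abundance=0.27,
        ),
        CellTypeProfile(
            "b",
            nadph=_chan(395, 2580, 0.75, 118),
            fad=_chan(350, 2290, 0.73, 100),
            area_px=(92, 0.18),
            abundance=0.15,
        ),
        CellTypeProfile(
            "nk",
            nadph=_chan(410, 2610, 0.72, 122),
            fad=_chan(320, 2250, 0.68, 108),
            area_px=(98, 0.18),
            abundance=0.13,
        ),
        CellTypeProfile(
            "monocyte",
            nadph=_chan(380, 2450, 0.82, 130),
            fad=_chan(360, 2320, 0.74, 95),
            area_px=(210, 0.20),
            abundance=0.15,
        ),
    ]


def effect_pair(
    d_target: float,
    variable_cv: float = 0.05,
    base_tau1: float = 400.0,
) -> list[CellTypeProfile]:
    """Two profiles whose NAD(P)H tau_m (and tau1) differ by Cohen's d.

    Between-cell variation is confined to NAD(P)H tau1 with equal absolute
    SD in both groups, so tau_m = alpha1*tau1 + const is linear in tau1 and
    the separation on tau_m is exactly ``d_target`` in expectation.
    """
    sd = variable_cv * base_tau1
    shifted = base_tau1 + d_target * sd

    def _prof(name: str, t1_mean: float) -> CellTypeProfile:
        return CellTypeProfile(
            name,
            nadph=ChannelDist(
                tau1=(t1_mean, sd / t1_mean),
                tau2=(2600, 0.0),
                alpha1_frac=(0.72, 0.0),
                photons_per_pixel=(120, 0.0),
            ),
            fad=ChannelDist(
                tau1=(350, 0.0),
                tau2=(2300, 0.0),
                alpha1_frac=(0.72, 0.0),
                photons_per_pixel=(100, 0.0),
            ),
            area_px=(95, 0.0),
            abundance=0.5,
        )

    return [_prof("group_a", base_tau1), _prof("group_b", shifted)]


def activated_profiles(
    base: list[CellTypeProfile] | None = None,
    strength: float = 1.0,
) -> list[CellTypeProfile]:
    """Shift profiles the way broad chemical activation shifts PBMCs.

    Lymphocytes drop in NAD(P)H mean lifetime (alpha1 rises) while
    monocytes move the opposite way; every type gains redox ratio (NAD(P)H
    intensity up) and loses NAD(P)H tau1.  ``strength`` scales the shifts
    (1.0 gives large, clearly separable effects for classifier studies).
    """
    base = base if base is not None else default_profiles()
    out = []
    for p in base:
        (t1m, t1c) = p.nadph.tau1
        (am, ac) = p.nadph.alpha1_frac
        (pm, pc) = p.nadph.photons_per_pixel
        if p.name == "monocyte":
            da = -0.05 * strength
        else:
            da = +0.06 * strength
        nadph = ChannelDist(
            tau1=(t1m - 30.0 * strength, t1c),
            tau2=p.nadph.tau2,
            alpha1_frac=(float(np.clip(am + da, 0.0, 1.0)), ac),
            photons_per_pixel=(pm * (1 + 0.15 * strength), pc),
            background_rate=p.nadph.background_rate,
        )
        out.append(
            CellTypeProfile(
                p.name, nadph=nadph, fad=p.fad, area_px=p.area_px,
                abundance=p.abundance,
            )
        )
    return out


def contrast_pair(d_taum: float = 2.0) -> list[CellTypeProfile]:
    """A lymphocyte-like / monocyte-like pair for end-to-end pipeline tests.

    The NAD(P)H tau_m gap is calibrated (delta method on the profile CVs) to
    ``d_taum`` pooled-SD units; the monocyte-like type additionally carries
    the higher NAD(P)H alpha1 and larger area that accompany that contrast
    in PBMCs.
    """
    lym = CellTypeProfile(
        "lymphocyte",
        nadph=_chan(400, 2600, 0.72, 120),
        fad=_chan(350, 2300, 0.72, 100),
        area_px=(95, 0.15),
        abundance=0.5,
    )

    def taum_sd(ch: ChannelDist) -> tuple[float, float]:
        (m1, c1), (m2, c2), (ma, ca) = ch.tau1, ch.tau2, ch.alpha1_frac
        mean = ma * m1 + (1 - ma) * m2
        var = (
            (ma * c1 * m1) ** 2
            + ((1 - ma) * c2 * m2) ** 2
            + ((m1 - m2) * ca * ma) ** 2
        )
        return mean, np.sqrt(var)

    mono_alpha = 0.80
    mono_tau2 = 2500.0
    # solve for the monocyte tau1 mean giving the target tau_m gap
    base_mean, base_sd = taum_sd(lym.nadph)
    target_taum = base_mean - d_taum * base_sd  # monocyte tau_m is the low one
    mono_tau1 = (target_taum - (1 - mono_alpha) * mono_tau2) / mono_alpha
    mono = CellTypeProfile(
        "monocyte",
        nadph=_chan(mono_tau1, mono_tau2, mono_alpha, 130),
        fad=_chan(360, 2320, 0.74, 95),
        area_px=(200, 0.15),
        abundance=0.5,
    )
    return [lym, mono]
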