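"""Seeded synthetic data with the statistical structure the analyses assume.

The raw field and aquarium data behind the study design are not
deposited, so every pipeline stage is exercised on generated inputs with
known truth:

* CSR (binomial) point patterns — the null of every spatial test;
* Thomas cluster processes — the aggregated alternative (Poisson parents,
  Poisson numbers of Gaussian-displaced offspring);
* quadrat surveys — binned patterns or i.i.d. Poisson / negative-binomial
  counts, each individual independently assigned to the buried layer;
* Bernoulli Y-tube assay outcomes with stimulus-dependent movement
  probability;
* presence/absence saponin profile sets in which designated marker
  compounds occur in every attractive sample and never in a
  non-attractive one, all other compounds appearing as background noise.

A single global seed fans out to per-component substreams through
``numpy.random.SeedSequence`` so adding a generator does not perturb
existing streams.

Default study-scale parameters mirror the field protocol: 10 pens
surveyed monthly for 7 months, 30 quadrats of 4 m² per survey, about
3 animals per quadrat with 69% of individuals buried; aquarium
experiments use 60 cm tanks with 10-40 juveniles.
"""

from __future__ import annotations

import numpy as np

from .assays import AssayRecord
from .patterns import PointPattern
from .quadrats import QuadratSurvey
from .saponins import SampleProfile, SaponinLibrary, SaponinProfileSet
from .windows import Disk, Rectangle, Window

# Field-survey geometry: 5 x 6 grid of 2 m x 2 m quadrats (30 of 4 m^2).
FIELD_GRID = (5, 6)
FIELD_QUADRAT_SIDE = 2.0  # m
FIELD_QUADRAT_AREA = FIELD_QUADRAT_SIDE**2
P_BURIED = 0.69  # observed aggregate buried fraction
FIELD_POISSON_MEAN = 3.0  # animals per quadrat under the random null
# Clustered alternative: a few tight clusters matching the overall density.
FIELD_PARENT_INTENSITY = 0.025  # parents per m^2 (~3 per 120 m^2 pen)
FIELD_MEAN_OFFSPRING = 33.0
FIELD_OFFSPRING_SD = 1.0  # m; clusters concentrate within about a quadrat

TANK = Disk((0.0, 0.0), 30.0)  # 60 cm diameter aquarium, coordinates in cm


def _spawn(seed, n):
    """Fan a seed (or SeedSequence) out into n independent substreams."""
    if isinstance(seed, np.random.SeedSequence):
        return seed.spawn(n)
    return np.random.SeedSequence(seed).spawn(n)


def gen_csr_pattern(n: int, window: Window, seed) -> PointPattern:
    """Exactly n points uniform over the window (binomial/CSR pattern)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = np.random.default_rng(seed)
    pts = window.sample_uniform(n, rng) if n else np.empty((0, 2))
    return PointPattern(pts, window)


def gen_thomas_pattern(
    parent_intensity: float,
    mean_offspring: float,
    offspring_sd: float,
    window: Window,
    seed,
) -> PointPattern:
    """Thomas cluster process restricted to the window.

    Parents form a Poisson process on the window dilated by
    4 x offspring_sd (so clusters whose parents fall just outside still
    contribute, avoiding edge-thinning); each parent gets a
    Poisson(mean_offspring) brood displaced by isotropic Gaussian noise
    with standard deviation offspring_sd, and only offspring inside the
    window are kept.
    """
    if parent_intensity <= 0 or mean_offspring <= 0 or offspring_sd <= 0:
        raise ValueError("Thomas-process parameters must all be positive")
    rng = np.random.default_rng(seed)
    dilated = window.dilate(4.0 * offspring_sd)
    n_parents = rng.poisson(parent_intensity * dilated.area)
    parents = dilated.sample_uniform(n_parents, rng)
    pts = []
    for px, py in parents:
        k = rng.poisson(mean_offspring)
        if k:
            off = rng.normal((px, py), offspring_sd, size=(k, 2))
            pts.append(off)
    if pts:
        xy = np.concatenate(pts)
        xy = xy[window.contains(xy)]
    else:
        xy = np.empty((0, 2))
    return PointPattern(xy, window)


def expected_thomas_points(
    parent_intensity: float, mean_offspring: float, offspring_sd: float, window: Window
) -> float:
    """Expected offspring count generated before window clipping."""
    return parent_intensity * window.dilate(4.0 * offspring_sd).area * mean_offspring


def _split_layers(counts: np.ndarray, p_buried: float, rng) -> tuple[np.ndarray, np.ndarray]:
    buried = rng.binomial(counts, p_buried)
    return counts - buried, buried


def gen_quadrat_counts(
    source,
    grid: tuple[int, int] = FIELD_GRID,
    mode: str = "poisson",
    seed=None,
    mu: float = FIELD_POISSON_MEAN,
    dispersion: float | None = None,
    p_buried: float = P_BURIED,
    pen_id: str = "pen",
    month: str = "m01",
    quadrat_area: float = FIELD_QUADRAT_AREA,
) -> QuadratSurvey:
    """A quadrat survey from a pattern ("bin") or i.i.d. counts.

    "bin" requires ``source`` to be a PointPattern on a rectangle whose
    extent matches the grid; "poisson" draws i.i.d. Poisson(mu) counts;
    "negbinom" draws overdispersed negative-binomial counts with shape
    ``dispersion`` (variance mu + mu^2/dispersion).  Each count is then
    split into surface/buried layers by an independent Bernoulli(p_buried)
    per individual.
    """
    rows, cols = grid
    if rows * cols < 2:
        raise ValueError("grid must have at least 2 cells")
    if not 0 <= p_buried <= 1:
        raise ValueError("p_buried must be a probability")
    rng = np.random.default_rng(seed)
    if mode == "bin":
        if not isinstance(source, PointPattern):
            raise TypeError('mode "bin" requires a PointPattern source')
        win = source.window
        if not isinstance(win, Rectangle):
            raise ValueError("binning requires a rectangular window")
        if not (
            np.isclose(win.width, cols * np.sqrt(quadrat_area))
            and np.isclose(win.height, rows * np.sqrt(quadrat_area))
        ):
            raise ValueError(
                f"window extent {win.width:g} x {win.height:g} does not match a "
                f"{rows} x {cols} grid of {quadrat_area:g}-area quadrats"
            )
        counts, _, _ = np.histogram2d(
            source.points[:, 1], source.points[:, 0],
            bins=[rows, cols],
            range=[[win.ymin, win.ymax], [win.xmin, win.xmax]],
        )
        counts = counts.astype(int)
    elif mode == "poisson":
        counts = rng.poisson(mu, size=(rows, cols))
    elif mode == "negbinom":
        if dispersion is None or dispersion <= 0:
            raise ValueError('mode "negbinom" requires dispersion > 0')
        p = dispersion / (dispersion + mu)
        counts = rng.negative_binomial(dispersion, p, size=(rows, cols))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    surface, buried = _split_layers(counts, p_buried, rng)
    return QuadratSurvey(pen_id, month, surface, buried, quadrat_area)


def field_window(grid: tuple[int, int] = FIELD_GRID) -> Rectangle:
    """Rectangular extent of a survey grid, in metres."""
    rows, cols = grid
    return Rectangle(0.0, cols * FIELD_QUADRAT_SIDE, 0.0, rows * FIELD_QUADRAT_SIDE)


def gen_field_survey(
    clustered: bool, seed, pen_id: str = "pen", month: str = "m01"
) -> QuadratSurvey:
    """One synthetic pen survey under the study's default conditions.

    ``clustered=False`` gives the Poisson null (mean 3 per quadrat);
    ``clustered=True`` bins a Thomas pattern with the default clustered
    parameters, yielding strongly overdispersed counts at a comparable
    overall density.
    """
    if not clustered:
        return gen_quadrat_counts(
            None, FIELD_GRID, "poisson", seed, mu=FIELD_POISSON_MEAN,
            pen_id=pen_id, month=month,
        )
    ss = _spawn(seed, 2)
    pattern = gen_thomas_pattern(
        FIELD_PARENT_INTENSITY, FIELD_MEAN_OFFSPRING, FIELD_OFFSPRING_SD,
        field_window(), ss[0],
    )
    return gen_quadrat_counts(
        pattern, FIELD_GRID, "bin", ss[1], pen_id=pen_id, month=month
    )


def gen_survey_campaign(
    clustered: bool = True, n_pens: int = 10, n_months: int = 7, seed=0
) -> list[QuadratSurvey]:
    """A full campaign: every pen surveyed every month (n_pens x n_months)."""
    seeds = _spawn(seed, n_pens * n_months)
    surveys = []
    for p in range(n_pens):
        for m in range(n_months):
            surveys.append(
                gen_field_survey(
                    clustered, seeds[p * n_months + m],
                    pen_id=f"G{p + 1:02d}", month=f"m{m + 1:02d}",
                )
            )
    return surveys


def gen_aquarium_experiments(
    densities: tuple[int, ...] = (25, 20, 10),
    n_replicates: int = 6,
    clustered: bool = False,
    seed=0,
) -> list[PointPattern]:
    """Overnight tank experiments: each density replicated in fresh tanks.

    Clustered tanks place the animals in three tight Thomas-style groups
    (the configuration seen once aggregation has formed); CSR tanks place
    them uniformly.
    """
    seeds = _spawn(seed, len(densities) * n_replicates)
    out = []
    i = 0
    for n in densities:
        for _ in range(n_replicates):
            if clustered:
                out.append(gen_clustered_tank(n, seeds[i]))
            else:
                out.append(gen_csr_pattern(n, TANK, seeds[i]))
            i += 1
    return out


def gen_clustered_tank(
    n: int, seed, n_clusters: int = 3, spread: float = 2.0, window: Disk = TANK
) -> PointPattern:
    """Exactly n animals in a few tight groups inside a tank.

    Cluster centres are placed uniformly in the inner disk (at least
    4 x spread from the wall when possible); each animal joins a uniformly
    chosen cluster and is displaced by isotropic Gaussian noise with SD
    ``spread`` (cm), resampled until inside the tank.  Mirrors the
    three-group configuration observed in aggregated tanks.
    """
    rng = np.random.default_rng(seed)
    inner = Disk(window.center, max(window.radius - 4.0 * spread, window.radius / 4))
    centers = inner.sample_uniform(n_clusters, rng)
    pts = np.empty((n, 2))
    labels = rng.integers(0, n_clusters, size=n)
    for i in range(n):
        while True:
            xy = rng.normal(centers[labels[i]], spread)
            if window.contains(xy[None, :])[0]:
                pts[i] = xy
                break
    return PointPattern(pts, window)


def gen_assay_outcomes(p_move: float, n_trials: int, seed, stimulus: str = "stimulus") -> AssayRecord:
    """Binomial movement outcome for one stimulus arm."""
    if not 0 <= p_move <= 1:
        raise ValueError("p_move must be a probability")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    moved = int(rng.binomial(n_trials, p_move))
    return AssayRecord(stimulus, moved, n_trials)


def gen_profiles(
    library: SaponinLibrary,
    n_attractive: int,
    n_nonattractive: int,
    marker_mzs,
    p_background: float,
    seed,
) -> SaponinProfileSet:
    """Profile set with markers confined to the attractive samples.

    Marker compounds are present in every attractive sample and absent
    from every non-attractive one; every other library compound occurs
    independently with probability p_background in any sample.
    """
    markers = {float(m) for m in marker_mzs}
    stray = markers - set(library._by_mz)
    if stray:
        raise ValueError(f"marker m/z not in library: {sorted(stray)}")
    if not 0 <= p_background <= 1:
        raise ValueError("p_background must be a probability")
    rng = np.random.default_rng(seed)
    others = [e.mz_na for e in library if e.mz_na not in markers]
    samples = []
    for i in range(n_attractive):
        detected = set(markers)
        detected.update(m for m in others if rng.random() < p_background)
        samples.append(SampleProfile(f"attractive_{i + 1}", True, detected))
    for i in range(n_nonattractive):
        detected = {m for m in others if rng.random() < p_background}
        samples.append(SampleProfile(f"nonattractive_{i + 1}", False, detected))
    return SaponinProfileSet(library, samples)
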