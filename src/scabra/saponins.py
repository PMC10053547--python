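"""Saponin presence/absence profiling and differential analysis.

MALDI peak lists (sodiated [M+Na]+ ions) are annotated against a
reference library of holothuroid saponins, each entry carrying one or
more isomeric names, its m/z, and its number of sugar residues (MALDI
cannot distinguish isomers, so entries are keyed on m/z).  Samples are
labelled attractive or non-attractive according to the behavioural
assays, and the differential question is which library entries are
present in the attractive profiles while absent from every
non-attractive one — the candidate chemoattractant set.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_TOLERANCE = 0.5  # m/z; library masses are given to one decimal


@dataclass(frozen=True)
class LibraryEntry:
    names: tuple[str, ...]
    mz_na: float
    n_sugars: int

    @property
    def nominal_mz(self) -> int:
        """Integer m/z for display, by truncation (905.4 -> 905)."""
        return int(self.mz_na)


class SaponinLibrary:
    """Reference library keyed on [M+Na]+ m/z."""

    def __init__(self, entries):
        entries = tuple(entries)
        mzs = [e.mz_na for e in entries]
        if len(set(mzs)) != len(mzs):
            raise ValueError("library m/z values must be unique")
        for e in entries:
            if e.mz_na <= 0:
                raise ValueError(f"non-positive m/z in library: {e.mz_na}")
            if e.n_sugars < 1:
                raise ValueError(f"entry {e.names}: n_sugars must be >= 1")
        self.entries = entries
        self._by_mz = {e.mz_na: e for e in entries}

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def mz_values(self) -> np.ndarray:
        return np.array([e.mz_na for e in self.entries])

    def __getitem__(self, mz: float) -> LibraryEntry:
        return self._by_mz[mz]

    def __contains__(self, mz: float) -> bool:
        return mz in self._by_mz


@dataclass(frozen=True)
class SampleProfile:
    sample_id: str
    attractive: bool
    detected: frozenset  # of library mz_na values

    def __post_init__(self) -> None:
        object.__setattr__(self, "detected", frozenset(self.detected))


class SaponinProfileSet:
    """A library plus the per-sample presence/absence profiles."""

    def __init__(self, library: SaponinLibrary, samples):
        samples = tuple(samples)
        ids = [s.sample_id for s in samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")
        for s in samples:
            stray = s.detected - set(library._by_mz)
            if stray:
                raise ValueError(
                    f"sample {s.sample_id!r} detects m/z not in the library: "
                    f"{sorted(stray)}"
                )
        self.library = library
        self.samples = samples

    @property
    def attractive_samples(self):
        return [s for s in self.samples if s.attractive]

    @property
    def nonattractive_samples(self):
        return [s for s in self.samples if not s.attractive]

    def sample(self, sample_id: str) -> SampleProfile:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)


def annotate_peaks(peaks, library: SaponinLibrary, tolerance: float = DEFAULT_TOLERANCE):
    """Assign raw peaks to nearest library entries within a mass tolerance.

    Each peak's candidate is its nearest library m/z; a peak further than
    ``tolerance`` from every entry is unmatched.  When two peaks claim the
    same entry the nearer peak wins and the other is returned unmatched
    (it is not reassigned to its second-nearest entry).

    Returns (detected, unmatched): a set of library mz_na values and the
    list of unassigned peak m/z values in input order.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    lib_mz = library.mz_values
    peak_list = [float(p) for p in peaks]
    # resolve in order of match quality so "nearest wins" is unambiguous
    order = sorted(range(len(peak_list)), key=lambda i: abs_delta(peak_list[i], lib_mz))
    claimed: set[float] = set()
    matched_idx: dict[int, float] = {}
    for i in order:
        deltas = np.abs(lib_mz - peak_list[i])
        j = int(np.argmin(deltas))
        entry_mz = float(lib_mz[j])
        if deltas[j] > tolerance or entry_mz in claimed:
            continue  # out of tolerance, or a nearer peak owns this entry
        claimed.add(entry_mz)
        matched_idx[i] = entry_mz
    unmatched = [p for i, p in enumerate(peak_list) if i not in matched_idx]
    return set(matched_idx.values()), unmatched


def abs_delta(peak: float, lib_mz: np.ndarray) -> float:
    return float(np.min(np.abs(lib_mz - peak)))


def attractive_unique(
    profiles: SaponinProfileSet,
    rule: str = "all-attractive",
    sugar_filter: int | None = None,
    focal_samples=None,
):
    """Library entries that discriminate attractive from non-attractive samples.

    An entry qualifies when it is absent from every non-attractive sample
    and present in the attractive samples per ``rule``: at least one of
    them ("any-attractive") or all of them ("all-attractive").  When
    ``focal_samples`` is given, the presence requirement is evaluated over
    those attractive samples only; ``sugar_filter`` restricts the result
    to entries with that number of sugar residues.

    Returns the qualifying entries sorted by descending m/z.
    """
    if rule not in ("any-attractive", "all-attractive"):
        raise ValueError(f"unknown rule {rule!r}")
    non_attr = profiles.nonattractive_samples
    attr = profiles.attractive_samples
    if not non_attr:
        raise ValueError("differential undefined: no non-attractive samples")
    if not attr:
        raise ValueError("differential undefined: no attractive samples")
    if focal_samples is not None:
        focal = set(focal_samples)
        known = {s.sample_id for s in attr}
        stray = focal - known
        if stray:
            raise ValueError(f"focal samples not among attractive samples: {sorted(stray)}")
        attr = [s for s in attr if s.sample_id in focal]

    blocked = set().union(*(s.detected for s in non_attr))
    out = []
    for entry in profiles.library:
        if sugar_filter is not None and entry.n_sugars != sugar_filter:
            continue
        if entry.mz_na in blocked:
            continue
        present = [entry.mz_na in s.detected for s in attr]
        ok = any(present) if rule == "any-attractive" else all(present)
        if ok and present:  # all() on empty focal set must not qualify
            out.append(entry)
    return sorted(out, key=lambda e: -e.mz_na)


def profile_matrix(profiles: SaponinProfileSet) -> pd.DataFrame:
    """Boolean entries x samples matrix, ordered by descending m/z.

    Sample attractiveness flags travel in ``df.attrs["attractive"]``.
    """
    entries = sorted(profiles.library, key=lambda e: -e.mz_na)
    data = {
        s.sample_id: [e.mz_na in s.detected for e in entries] for s in profiles.samples
    }
    df = pd.DataFrame(data, index=[e.mz_na for e in entries])
    df.index.name = "mz_na"
    df.attrs["attractive"] = {s.sample_id: s.attractive for s in profiles.samples}
    return df


def diversity_summary(profiles: SaponinProfileSet) -> pd.DataFrame:
    """Per-sample detected-compound counts, split by sugar-residue class."""
    classes = sorted({e.n_sugars for e in profiles.library})
    rows = []
    for s in profiles.samples:
        row = {"sample_id": s.sample_id, "attractive": s.attractive,
               "n_detected": len(s.detected)}
        for c in classes:
            row[f"sugars_{c}"] = sum(
                1 for e in profiles.library if e.n_sugars == c and e.mz_na in s.detected
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("sample_id")


# ---------------------------------------------------------------------------
# Packaged reference fixture: the published presence/absence matrix of the
# five assayed extracts against the 16-entry saponin library.

JUVENILE_INTEGUMENT = "H. scabra juvenile integument"
STARVED_INTEGUMENT = "H. scabra starved juvenile integument"
ADULT_VISCERA = "H. scabra adult viscera"
ADULT_CONDITIONED_WATER = "H. scabra adult conditioned water"
LEUCOSPILOTA_MUCUS = "H. leucospilota BW mucus"


def load_reference_library() -> SaponinLibrary:
    """The packaged 16-entry saponin reference library."""
    path = resources.files("scabra.data").joinpath("saponin_library.csv")
    with resources.as_file(path) as f:
        df = pd.read_csv(f)
    entries = [
        LibraryEntry(tuple(r["names"].split("|")), float(r["mz_na"]), int(r["n_sugars"]))
        for _, r in df.iterrows()
    ]
    return SaponinLibrary(entries)


def load_reference_profiles() -> SaponinProfileSet:
    """The packaged five-sample presence/absence matrix.

    Attractive samples (induced significant movement in the assays):
    healthy juvenile integument, adult viscera, *H. leucospilota* body-wall
    mucus.  Non-attractive: starved juvenile integument and adult
    conditioned water.
    """
    library = load_reference_library()
    path = resources.files("scabra.data").joinpath("reference_profiles.csv")
    with resources.as_file(path) as f:
        df = pd.read_csv(f)
    samples = []
    for _, r in df.iterrows():
        detected = frozenset(
            float(v) for v in str(r["detected_mz"]).split() if v
        ) if pd.notna(r["detected_mz"]) and str(r["detected_mz"]).strip() else frozenset()
        samples.append(
            SampleProfile(r["sample_id"], bool(r["attractive"]), detected)
        )
    return SaponinProfileSet(library, samples)
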