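"""Camera-trap record ingestion and detection-history construction.

A camera-trap survey produces a stream of timestamped image records per
station.  This module turns that stream into the count matrix that
occupancy models consume: records are thinned to *independent* events
(same species at the same station must be at least a fixed interval
apart), small hard-to-identify taxa may be clumped into group labels,
and the surviving events are binned into survey occasions to give, for
every species k and site i, the number of occasions with at least one
detection (``y_ik``) out of ``n_i`` active occasions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

RECORD_COLUMNS = ("site", "kind", "species", "timestamp")
KINDS = ("wildlife", "human", "livestock", "blank", "unidentified")

__all__ = [
    "DetectionHistory",
    "read_camera_records",
    "read_deployments",
    "aggregate_taxa",
    "filter_independent",
    "build_detection_history",
    "detection_categories",
    "naive_estimates",
    "image_category_percentages",
]


@dataclass
class DetectionHistory:
    """Site-aggregated detection counts for the observed community.

    Attributes
    ----------
    species : list of str
        Observed taxa (every row has at least one detection).
    sites : list
        Site identifiers, in deployment order.
    y : ndarray of shape (K, I)
        Number of occasions with >=1 independent detection of species k
        at site i.
    n : ndarray of shape (I,)
        Active occasions per site (default unit: one occasion = one day).
    occasion_days : int
        Length of one occasion in days.
    """

    species: list
    sites: list
    y: np.ndarray
    n: np.ndarray
    occasion_days: int = 1

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=int)
        self.n = np.asarray(self.n, dtype=int)
        if self.y.shape != (len(self.species), len(self.sites)):
            raise ValueError("y must be K x I")
        if np.any(self.n < 1):
            raise ValueError("every site needs n_i >= 1")
        if np.any(self.y < 0) or np.any(self.y > self.n[None, :]):
            raise ValueError("detection counts must satisfy 0 <= y_ik <= n_i")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def to_frame(self) -> pd.DataFrame:
        """Wide layout: rows species, columns sites."""
        return pd.DataFrame(self.y, index=pd.Index(self.species, name="species"),
                            columns=self.sites)

    def effort_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"site": self.sites, "n_occasions": self.n})

    def to_csv(self, history_path, effort_path) -> None:
        self.to_frame().to_csv(history_path)
        self.effort_frame().to_csv(effort_path, index=False)

    @classmethod
    def from_csv(cls, history_path, effort_path, occasion_days: int = 1
                 ) -> "DetectionHistory":
        wide = pd.read_csv(history_path, index_col=0)
        effort = pd.read_csv(effort_path)
        effort = effort.set_index(effort["site"].astype(str))
        n = effort.loc[[str(c) for c in wide.columns], "n_occasions"].to_numpy()
        return cls(species=list(wide.index), sites=list(wide.columns),
                   y=wide.to_numpy(), n=n, occasion_days=occasion_days)


def read_camera_records(path) -> pd.DataFrame:
    """Read a camera-trap record table from delimited text.

    Required columns: ``site``, ``kind``, ``species``, ``timestamp``.
    Timestamps are parsed to the second; a row that fails to parse is
    reported with its line number.
    """
    df = pd.read_csv(path, dtype={"site": str, "kind": str, "species": str})
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"record table {path} is missing column(s): "
                         + ", ".join(missing))
    parsed = pd.to_datetime(df["timestamp"], errors="coerce", format="mixed")
    bad = np.flatnonzero(parsed.isna() & df["timestamp"].notna())
    if bad.size:
        # +2: header line plus 1-based indexing
        lines = ", ".join(str(i + 2) for i in bad[:10])
        raise ValueError(
            f"unparseable timestamp(s) in {path} at line(s) {lines}"
            + (" ..." if bad.size > 10 else ""))
    df = df.copy()
    df["timestamp"] = parsed
    unknown = set(df["kind"].dropna()) - set(KINDS)
    if unknown:
        raise ValueError(f"unknown record kind(s): {sorted(unknown)}")
    return df


def read_deployments(path) -> pd.DataFrame:
    """Read the deployment table (site, x, y, start, end); dates inclusive."""
    df = pd.read_csv(path, dtype={"site": str})
    missing = [c for c in ("site", "x", "y", "start", "end") if c not in df.columns]
    if missing:
        raise ValueError(f"deployment table {path} is missing column(s): "
                         + ", ".join(missing))
    df = df.copy()
    df["start"] = pd.to_datetime(df["start"]).dt.normalize()
    df["end"] = pd.to_datetime(df["end"]).dt.normalize()
    if (df["end"] < df["start"]).any():
        bad = df.loc[df["end"] < df["start"], "site"].tolist()
        raise ValueError(f"end before start for site(s): {bad}")
    if df["site"].duplicated().any():
        raise ValueError("duplicate site ids in deployment table")
    return df


def aggregate_taxa(records: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Replace species labels by group labels (e.g. clump mice as 'Mouse spp.').

    Labels absent from ``mapping`` pass through unchanged; record count is
    preserved.
    """
    out = records.copy()
    out["species"] = out["species"].map(lambda s: mapping.get(s, s))
    return out


def _stream_key(records: pd.DataFrame) -> pd.Series:
    """Independence stream: species for wildlife, kind otherwise."""
    wildlife = records["kind"].eq("wildlife")
    return records["species"].where(wildlife, records["kind"]).astype(str)


def filter_independent(records: pd.DataFrame,
                       window_minutes: float = 60.0) -> pd.DataFrame:
    """Thin records to independent events (greedy-from-first rule).

    Within each (site, species) stream — (site, kind) for non-wildlife —
    processed in time order, a record is kept iff at least
    ``window_minutes`` have elapsed since the previously *kept* record of
    that stream.  A gap of exactly ``window_minutes`` counts as
    independent.  Output preserves the original row order.
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be non-negative")
    df = records.reset_index(drop=True)
    stream = _stream_key(df)
    window = pd.Timedelta(minutes=float(window_minutes))
    keep = np.zeros(len(df), dtype=bool)
    order = df["timestamp"].sort_values(kind="mergesort").index
    for _, idx in pd.Series(order).groupby(
            [df["site"].reindex(order).to_numpy(),
             stream.reindex(order).to_numpy()], sort=False):
        last = None
        for i in idx:
            ts = df.at[i, "timestamp"]
            if last is None or ts - last >= window:
                keep[i] = True
                last = ts
    return df.loc[keep].copy()


def build_detection_history(records: pd.DataFrame,
                            deployments: pd.DataFrame,
                            occasion_days: int = 1) -> DetectionHistory:
    """Bin independent wildlife records into per-occasion detection counts.

    ``n_i`` is the number of whole occasions in the inclusive deployment
    window (floor division: a trailing partial occasion is dropped when
    ``occasion_days > 1``); ``y_ik`` counts occasions at site i with at
    least one record of species k.  Records must already be
    independence-filtered; only ``kind == 'wildlife'`` rows contribute.
    """
    if occasion_days < 1:
        raise ValueError("occasion_days must be a positive integer")
    sites = list(deployments["site"])
    site_ix = {s: j for j, s in enumerate(sites)}
    unknown = sorted(set(records["site"]) - set(sites))
    if unknown:
        raise ValueError(f"record(s) reference unknown site(s): {unknown}")

    start = deployments.set_index("site")["start"]
    end = deployments.set_index("site")["end"]
    active_days = (end - start).dt.days + 1
    n = (active_days // occasion_days).reindex(sites).to_numpy()

    rec_start = records["site"].map(start)
    rec_day = (records["timestamp"].dt.normalize() - rec_start).dt.days
    rec_end_day = records["site"].map(end - start).dt.days
    outside = (rec_day < 0) | (rec_day > rec_end_day)
    if outside.any():
        bad = records.loc[outside, ["site", "species", "timestamp"]]
        raise ValueError(
            "record(s) outside their deployment window:\n"
            + bad.to_string(index=False))

    wl = records.loc[records["kind"].eq("wildlife")].copy()
    if wl["species"].isna().any():
        raise ValueError("wildlife record without species label")
    wl["occasion"] = (rec_day.loc[wl.index] // occasion_days).astype(int)
    # drop events falling in a trailing partial occasion
    wl = wl.loc[wl["occasion"] < wl["site"].map(dict(zip(sites, n)))]

    species = sorted(wl["species"].unique())
    y = np.zeros((len(species), len(sites)), dtype=int)
    if len(wl):
        uniq = wl.drop_duplicates(["species", "site", "occasion"])
        for sp, site in zip(uniq["species"], uniq["site"]):
            y[species.index(sp), site_ix[site]] += 1
    return DetectionHistory(species=species, sites=sites, y=y, n=n,
                            occasion_days=occasion_days)


_CATEGORY_ORDER = ("Abundant", "Common", "Uncommon", "Rare", "Undetected")


def detection_categories(history: DetectionHistory,
                         est_richness: int) -> pd.DataFrame:
    """Bin species by total detections: >100 abundant, 11-100 common,
    2-10 uncommon, 1 rare; undetected = est_richness - K."""
    if est_richness < history.n_species:
        raise ValueError("est_richness must be >= number of observed species")
    totals = history.y.sum(axis=1)
    counts = {
        "Abundant": int(np.sum(totals > 100)),
        "Common": int(np.sum((totals >= 11) & (totals <= 100))),
        "Uncommon": int(np.sum((totals >= 2) & (totals <= 10))),
        "Rare": int(np.sum(totals == 1)),
        "Undetected": int(est_richness - history.n_species),
    }
    return pd.DataFrame({"category": list(_CATEGORY_ORDER),
                         "species_count": [counts[c] for c in _CATEGORY_ORDER]})


def naive_estimates(history: DetectionHistory) -> pd.DataFrame:
    """Model-free occupancy and detection rates, uncorrected for
    imperfect detection.

    naive_psi_k = fraction of sites with >=1 detection;
    naive_p_k   = total detections / total trap effort (sum of n_i).
    """
    sites_with = (history.y > 0).sum(axis=1)
    return pd.DataFrame({
        "species": history.species,
        "naive_psi": sites_with / history.n_sites,
        "naive_p": history.y.sum(axis=1) / history.n.sum(),
    })


def image_category_percentages(counts: dict) -> pd.DataFrame:
    """Percent composition of image categories from raw counts."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    return pd.DataFrame({
        "category": list(counts),
        "count": list(counts.values()),
        "percent": [100.0 * c / total for c in counts.values()],
    })
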