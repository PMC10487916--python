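"""Copy-number aberration calling and recurrent-region selection.

A gain (loss) is called as a maximal run of at least ``min_probes``
consecutive probes on one chromosome whose log2 ratios are all at or above
the gain threshold (at or below the loss threshold).  Calls are aggregated
into per-cytoband penetrance — each case counts at most once per band and
direction — and bands at or above a recurrence-frequency cutoff are merged,
when adjacent and same-direction, into recurrent regions onto which gene and
miRNA annotations are mapped by 1-bp interval overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import GenomicInterval


@dataclass
class ProbeTrack:
    """One case's ordered array probes with log2(test/reference) ratios."""

    case_id: str
    probes: pd.DataFrame  # columns: chrom, start, stop, log2_ratio

    def __post_init__(self) -> None:
        required = {"chrom", "start", "stop", "log2_ratio"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")
        for chrom, grp in self.probes.groupby("chrom", sort=False):
            starts = grp["start"].to_numpy()
            if not (np.diff(starts) > 0).all():
                raise ValueError(
                    f"track {self.case_id}: probes on {chrom} unsorted or duplicated"
                )


@dataclass(frozen=True)
class CnaCall:
    """One contiguous gain/loss call in one case."""

    case_id: str
    interval: GenomicInterval
    direction: str  # gain | loss
    n_probes: int
    mean_log2: float


@dataclass(frozen=True)
class RecurrentRegion:
    """A cytoband-aligned region altered in multiple cases."""

    interval: GenomicInterval
    direction: str
    n_cases: int
    frequency: float
    n_probes: int
    bands: tuple[str, ...] = field(default=())

    @property
    def cytoband(self) -> str:
        if not self.bands:
            return ""
        return self.bands[0] if len(self.bands) == 1 else f"{self.bands[0]}-{self.bands[-1]}"


def call_aberrations(
    track: ProbeTrack,
    min_probes: int = 3,
    gain_threshold: float = 0.25,
    loss_threshold: float = -0.25,
) -> list[CnaCall]:
    """Call maximal qualifying probe runs as gains and losses.

    A run qualifies when every probe's log2 ratio is >= ``gain_threshold``
    (gain) or <= ``loss_threshold`` (loss) — boundary values included — and
    the run spans at least ``min_probes`` consecutive probes of the same
    chromosome.  A single sub-threshold probe terminates a run.  The call
    interval spans the first probe's start to the last probe's stop, and
    mean_log2 is the arithmetic mean over the run.
    """
    if min_probes < 1:
        raise ValueError("min_probes must be >= 1")
    if not (gain_threshold > 0 > loss_threshold):
        raise ValueError("need gain_threshold > 0 > loss_threshold")

    calls: list[CnaCall] = []
    for chrom, grp in track.probes.groupby("chrom", sort=False):
        log2 = grp["log2_ratio"].to_numpy(dtype=float)
        starts = grp["start"].to_numpy()
        stops = grp["stop"].to_numpy()
        for direction, mask in (
            ("gain", log2 >= gain_threshold),
            ("loss", log2 <= loss_threshold),
        ):
            # maximal runs of True in mask
            padded = np.concatenate([[False], mask, [False]])
            edges = np.flatnonzero(np.diff(padded.astype(int)))
            for i0, i1 in zip(edges[::2], edges[1::2]):  # [i0, i1) run
                if i1 - i0 < min_probes:
                    continue
                calls.append(
                    CnaCall(
                        case_id=track.case_id,
                        interval=GenomicInterval(chrom, int(starts[i0]), int(stops[i1 - 1])),
                        direction=direction,
                        n_probes=int(i1 - i0),
                        mean_log2=float(log2[i0:i1].mean()),
                    )
                )
    calls.sort(key=lambda c: (c.interval.chromosome, c.interval.start, c.direction))
    return calls


def aggregate_penetrance(
    calls_by_case: dict[str, list[CnaCall]],
    bands: list[tuple[str, GenomicInterval]],
    n_cases: int,
) -> pd.DataFrame:
    """Per-(cytoband, direction) case counts and frequencies.

    A case contributes at most once per band and direction no matter how many
    of its calls overlap the band.  ``n_probes`` reports the largest number
    of aberrant probes any single case's overlapping calls contribute to the
    band.  Returns one row per (band, direction) with a nonzero count,
    ordered by band then direction.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    if not bands:
        raise ValueError("band list is empty")

    rows = []
    for band_idx, (name, band_iv) in enumerate(bands):
        for direction in ("gain", "loss"):
            hit_cases = []
            probe_tallies = []
            for case_id in sorted(calls_by_case):
                overlapping = [
                    c
                    for c in calls_by_case[case_id]
                    if c.direction == direction and c.interval.overlaps(band_iv)
                ]
                if overlapping:
                    hit_cases.append(case_id)
                    probe_tallies.append(sum(c.n_probes for c in overlapping))
            if hit_cases:
                rows.append(
                    {
                        "band": name,
                        "band_index": band_idx,
                        "chrom": band_iv.chromosome,
                        "start": band_iv.start,
                        "stop": band_iv.stop,
                        "direction": direction,
                        "n_cases": len(hit_cases),
                        "frequency": len(hit_cases) / n_cases,
                        "n_probes": max(probe_tallies),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "band",
            "band_index",
            "chrom",
            "start",
            "stop",
            "direction",
            "n_cases",
            "frequency",
            "n_probes",
        ],
    )


def select_recurrent_regions(
    penetrance: pd.DataFrame, min_frequency: float = 0.19
) -> list[RecurrentRegion]:
    """Keep bands at or above ``min_frequency`` and merge adjacent ones.

    Bands that are genomically adjacent (consecutive in the cytoband list),
    share a chromosome and direction, and both pass the cutoff are merged
    into a single region spanning them; the merged region reports the maximum
    case count/frequency and the summed probe tally of its member bands.
    """
    if not 0 < min_frequency <= 1:
        raise ValueError("min_frequency must be in (0, 1]")
    kept = penetrance[penetrance["frequency"] >= min_frequency]
    regions: list[RecurrentRegion] = []
    for direction in ("gain", "loss"):
        sub = kept[kept["direction"] == direction].sort_values("band_index")
        run: list[pd.Series] = []
        for _, row in sub.iterrows():
            if run and (
                row["chrom"] != run[-1]["chrom"]
                or row["band_index"] != run[-1]["band_index"] + 1
            ):
                regions.append(_merge_band_run(run, direction))
                run = []
            run.append(row)
        if run:
            regions.append(_merge_band_run(run, direction))
    regions.sort(key=lambda r: (r.interval.chromosome, r.interval.start, r.direction))
    return regions


def _merge_band_run(run: list[pd.Series], direction: str) -> RecurrentRegion:
    return RecurrentRegion(
        interval=GenomicInterval(
            run[0]["chrom"], int(run[0]["start"]), int(run[-1]["stop"])
        ),
        direction=direction,
        n_cases=int(max(r["n_cases"] for r in run)),
        frequency=float(max(r["frequency"] for r in run)),
        n_probes=int(sum(r["n_probes"] for r in run)),
        bands=tuple(r["band"] for r in run),
    )


def map_features_to_regions(
    annotations: dict[str, GenomicInterval], regions: list[RecurrentRegion]
) -> dict[str, list[RecurrentRegion]]:
    """Map features onto recurrent regions by >= 1 bp interval overlap.

    A feature may hit multiple regions.  Features on chromosomes absent from
    every region simply produce no hits.  Output keys are sorted feature ids;
    only features with at least one hit appear.
    """
    hits: dict[str, list[RecurrentRegion]] = {}
    for fid in sorted(annotations):
        iv = annotations[fid]
        matched = [r for r in regions if r.interval.overlaps(iv)]
        if matched:
            hits[fid] = matched
    return hits
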