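"""Lipid dwell events and residence-time statistics.

A dwell event is one maximal run of consecutive frames in which a given
residue-lipid pair is in contact.  Its residence time is literally the time
difference between the first and last frame of the run,

    t_res = t_f - t_i = (k - 1) * dt

for a k-frame run, so a single-frame contact has t_res = 0.  This is the
first/last-time convention, not the "occupancy time" k*dt; the two differ by
exactly one frame spacing per event.  The aggregate residence time of a
residue is the sum of t_res over its events.

Events truncated by either end of the trajectory are flagged ``censored``;
they contribute to aggregate residence time but are excluded from mean-dwell
estimates, which would otherwise be biased low.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contacts import ContactSeries, ContactSummary, contact_probability, stable_residues
from .model_io import ResidueKey

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DwellEvent:
    """One contiguous residue-lipid contact interval."""

    residue: ResidueKey
    lipid: ResidueKey
    species: str
    start_frame: int
    end_frame: int       # inclusive
    t_i: float           # ps
    t_f: float           # ps
    censored: bool       # touches either trajectory end

    @property
    def t_res(self) -> float:
        return self.t_f - self.t_i

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


def _runs(mask: np.ndarray):
    """Start/end (inclusive) indices of maximal True runs in a 1D bool array."""
    idx = np.nonzero(mask)[0]
    if idx.size == 0:
        return []
    breaks = np.nonzero(np.diff(idx) > 1)[0]
    starts = np.concatenate(([idx[0]], idx[breaks + 1]))
    ends = np.concatenate((idx[breaks], [idx[-1]]))
    return list(zip(starts.tolist(), ends.tolist()))


def dwell_events(series: ContactSeries,
                 species_filter: str | None = None,
                 eligible_residues: set[ResidueKey] | None = None,
                 gap_frames: int = 0,
                 stability_threshold: float = 0.5) -> list[DwellEvent]:
    """Extract dwell events from a contact record.

    By default only residues in membrane contact for more than
    ``stability_threshold`` (50%) of the frames are examined, mirroring the
    convention of computing lipid residence times only around stably bound
    residues.  Pass ``eligible_residues=set of keys`` to override, or the
    full residue set to disable the filter.

    ``gap_frames`` > 0 bridges interruptions of at most that many frames
    inside one event (off by default: an event admits no gaps).
    """
    if gap_frames < 0:
        raise ValueError("gap_frames must be >= 0")
    if eligible_residues is None:
        summary = contact_probability(series)
        eligible_residues = stable_residues(summary, stability_threshold)

    lipid_sel = range(len(series.lipid_keys))
    if species_filter is not None:
        lipid_sel = [i for i in lipid_sel
                     if series.lipid_species[i] == species_filter]
        if not lipid_sel:
            logger.warning("species filter %r matches no lipids", species_filter)
            return []

    nf = series.n_frames
    events: list[DwellEvent] = []
    for ri, rkey in enumerate(series.residue_keys):
        if rkey not in eligible_residues:
            continue
        for li in lipid_sel:
            mask = series.contact[ri, li]
            runs = _runs(mask)
            if gap_frames > 0 and len(runs) > 1:
                merged = [runs[0]]
                for s, e in runs[1:]:
                    if s - merged[-1][1] - 1 <= gap_frames:
                        merged[-1] = (merged[-1][0], e)
                    else:
                        merged.append((s, e))
                runs = merged
            for s, e in runs:
                events.append(DwellEvent(
                    residue=rkey,
                    lipid=series.lipid_keys[li],
                    species=series.lipid_species[li],
                    start_frame=int(s), end_frame=int(e),
                    t_i=s * series.dt, t_f=e * series.dt,
                    censored=(s == 0 or e == nf - 1),
                ))
    events.sort(key=lambda ev: (ev.residue, ev.lipid, ev.start_frame))
    return events


@dataclass
class ResidenceSummary:
    """Residence-time statistics over a set of dwell events."""

    events: list[DwellEvent]
    hist_counts: np.ndarray
    hist_edges: np.ndarray       # ps
    t_res_max: float             # ps, over all events
    aggregate: float             # ps, sum of t_res over all events
    n_long_events: int           # events with t_res >= min_event_ps
    min_event_ps: float
    per_residue: pd.DataFrame    # residue, n_events, t_res_max_ps, aggregate_ps
    mean_dwell: float            # ps, uncensored events only (nan if none)

    def events_table(self) -> pd.DataFrame:
        rows = [{
            "chain": ev.residue[0], "resnum": ev.residue[1],
            "lipid_chain": ev.lipid[0], "lipid_id": ev.lipid[1],
            "species": ev.species, "t_i_ps": ev.t_i, "t_f_ps": ev.t_f,
            "t_res_ps": ev.t_res, "censored": ev.censored,
        } for ev in self.events]
        return pd.DataFrame(rows)


def residence_summary(events: list[DwellEvent],
                      min_event_ps: float = 40_000.0,
                      bin_width_ps: float = 10_000.0) -> ResidenceSummary:
    """Histogram of t_res, maxima, aggregate, and long-event counts.

    ``min_event_ps`` (default 40 ns) counts binding events with
    t_res >= threshold, inclusive.  Histogram bins are ``bin_width_ps`` wide
    (default 10 ns).
    """
    if min_event_ps < 0:
        raise ValueError("min_event_ps must be >= 0")
    if bin_width_ps <= 0:
        raise ValueError("bin_width_ps must be positive")

    tres = np.array([ev.t_res for ev in events], dtype=float)
    if tres.size:
        upper = max(bin_width_ps, float(tres.max()))
        nbins = int(np.ceil(upper / bin_width_ps))
        edges = np.arange(nbins + 1) * bin_width_ps
        # right edge inclusive for the last bin
        counts, edges = np.histogram(tres, bins=edges)
        t_max = float(tres.max())
        agg = float(tres.sum())
    else:
        edges = np.array([0.0, bin_width_ps])
        counts = np.zeros(1, dtype=int)
        t_max = 0.0
        agg = 0.0

    uncens = [ev.t_res for ev in events if not ev.censored]
    mean_dwell = float(np.mean(uncens)) if uncens else float("nan")

    per_res: dict[ResidueKey, list[DwellEvent]] = {}
    for ev in events:
        per_res.setdefault(ev.residue, []).append(ev)
    rows = [{
        "chain": k[0], "resnum": k[1], "n_events": len(evs),
        "t_res_max_ps": max(ev.t_res for ev in evs),
        "aggregate_ps": sum(ev.t_res for ev in evs),
    } for k, evs in sorted(per_res.items())]

    return ResidenceSummary(
        events=events,
        hist_counts=counts, hist_edges=edges,
        t_res_max=t_max, aggregate=agg,
        n_long_events=int(np.sum(tres >= min_event_ps)),
        min_event_ps=min_event_ps,
        per_residue=pd.DataFrame(rows),
        mean_dwell=mean_dwell,
    )


def stride_sensitivity(series: ContactSeries, strides: list[int],
                       species_filter: str | None = None,
                       eligible_residues: set[ResidueKey] | None = None,
                       min_event_ps: float = 40_000.0
                       ) -> dict[int, ResidenceSummary]:
    """Recompute residence statistics on frame-subsampled contact records.

    Subsampling with stride s yields an effective frame spacing s*dt; gaps
    shorter than the stride become invisible, so coarser sampling can only
    merge events and residence times are systematically sensitive to the
    sampling interval.
    """
    out = {}
    for s in strides:
        if s < 1:
            raise ValueError("stride must be >= 1")
        sub = series.subsample(s) if s > 1 else series
        evs = dwell_events(sub, species_filter=species_filter,
                           eligible_residues=eligible_residues)
        out[s] = residence_summary(evs, min_event_ps=min_event_ps)
    return out
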