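"""Linking of per-frame detections into adhesion trajectories.

Frame-to-frame correspondence is solved as a global linear assignment on
squared displacement, with explicit birth/death alternatives priced at the
squared search radius (so a link farther than the radius is never
preferred over starting a new track). Broken tracks are re-joined by a
second assignment pass (gap closing) across up to ``max_gap`` missing
frames. Every detection ends up in exactly one track; detections that link
to nothing become singleton tracks, so track lengths always sum to the
detection count.

Each trajectory carries a per-frame maturation status against the FC/FA
segmentation: ``NA`` while detected outside any FC/FA region, ``FC``/``FA``
while inside one, and ``BA`` (before adhesion) for movie frames preceding
the first detection when the track is viewed on the full movie timeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detection import PointDetection
from .segmentation import AdhesionRegion, class_map

BA, NA, FC, FA = "BA", "NA", "FC", "FA"
_BIG = 1e12


@dataclass
class AdhesionTrack:
    """A linked trajectory with per-frame adhesion status."""

    id: int
    points: list[tuple[int, float, float, float]]  # (frame, x, y, amplitude)
    status_sequence: list[str] = field(default_factory=list)

    @property
    def first_frame(self) -> int:
        return self.points[0][0]

    @property
    def last_frame(self) -> int:
        return self.points[-1][0]

    @property
    def n_frames(self) -> int:
        """Frame span including gap-closed frames."""
        return self.last_frame - self.first_frame + 1

    @property
    def matured(self) -> bool:
        return any(s in (FC, FA) for s in self.status_sequence)

    def lifetime(self, frame_interval: float) -> float:
        """Track lifetime in seconds: (frame span) × frame interval."""
        return self.n_frames * frame_interval

    def status_timeline(self, frame_count: int) -> list[str]:
        """Status on the full movie timeline; BA before the first detection."""
        by_frame = {p[0]: s for p, s in zip(self.points, self.status_sequence)}
        out = []
        for f in range(frame_count):
            if f < self.first_frame:
                out.append(BA)
            else:
                out.append(by_frame.get(f, NA))
        return out


def _assign(cost: np.ndarray, alt_row: np.ndarray, alt_col: np.ndarray):
    """Solve assignment with per-row/col opt-out costs (birth/death).

    Returns list of (i, j) links chosen over the opt-out alternatives.
    """
    n, m = cost.shape
    full = np.full((n + m, m + n), _BIG)
    full[:n, :m] = cost
    full[:n, m:] = _BIG
    full[n:, :m] = _BIG
    full[:n, m:][np.diag_indices(n)] = alt_row
    full[n:, :m][np.diag_indices(m)] = alt_col
    full[n:, m:] = cost.T if n and m else 0.0
    rows, cols = linear_sum_assignment(full)
    return [(r, c) for r, c in zip(rows, cols)
            if r < n and c < m and cost[r, c] < _BIG]


def link_detections(detections: list[PointDetection], search_radius: float = 3.0,
                    max_gap: int = 2) -> list[AdhesionTrack]:
    """Link detections into tracks by global frame-to-frame assignment.

    ``search_radius`` (pixels) gates candidate links; cost is squared
    displacement and the no-link alternative costs ``search_radius²``.
    Gap closing joins a track end at frame f to a track start at frame
    f + g + 1 for g = 1 … ``max_gap``, within ``search_radius × (g + 1)``.
    """
    if search_radius < 0 or max_gap < 0:
        raise ValueError("search_radius and max_gap must be non-negative")
    dets = sorted(detections, key=lambda d: d.frame)
    if not dets:
        return []
    frames = sorted({d.frame for d in dets})
    by_frame = {f: [d for d in dets if d.frame == f] for f in frames}

    # frame-to-frame linking
    tracks: list[list[PointDetection]] = [[d] for d in by_frame[frames[0]]]
    active = list(range(len(tracks)))
    for fprev, fcur in zip(frames[:-1], frames[1:]):
        cur = by_frame[fcur]
        prev_tracks = [t for t in active
                       if tracks[t][-1].frame == fprev]
        if fcur != fprev + 1:
            prev_tracks = []  # only consecutive frames link here
        cost = np.full((len(prev_tracks), len(cur)), _BIG)
        for i, t in enumerate(prev_tracks):
            tp = tracks[t][-1]
            for j, d in enumerate(cur):
                d2 = (tp.x - d.x) ** 2 + (tp.y - d.y) ** 2
                if d2 <= search_radius ** 2:
                    cost[i, j] = d2
        alt = np.full(max(len(prev_tracks), 1), search_radius ** 2)
        links = _assign(cost, alt[:len(prev_tracks)],
                        np.full(len(cur), search_radius ** 2)) \
            if prev_tracks and cur else []
        linked_j = set()
        for i, j in links:
            tracks[prev_tracks[i]].append(cur[j])
            linked_j.add(j)
        for j, d in enumerate(cur):
            if j not in linked_j:
                tracks.append([d])
        active = list(range(len(tracks)))

    # gap closing: ends -> starts across 2 .. max_gap+1 frame differences
    if max_gap > 0:
        tracks = _close_gaps(tracks, search_radius, max_gap)

    return [AdhesionTrack(id=i, points=[(d.frame, d.x, d.y, d.amplitude)
                                        for d in tr])
            for i, tr in enumerate(tracks)]


def _close_gaps(tracks, search_radius, max_gap):
    ends = [(i, tr[-1]) for i, tr in enumerate(tracks)]
    starts = [(i, tr[0]) for i, tr in enumerate(tracks)]
    cost = np.full((len(ends), len(starts)), _BIG)
    for a, (i, e) in enumerate(ends):
        for b, (j, s) in enumerate(starts):
            gap = s.frame - e.frame
            if i == j or not (2 <= gap <= max_gap + 1):
                continue
            d2 = (e.x - s.x) ** 2 + (e.y - s.y) ** 2
            if d2 <= (search_radius * gap) ** 2:
                cost[a, b] = d2
    alt = np.full(len(ends), search_radius ** 2)
    links = _assign(cost, alt, np.full(len(starts), search_radius ** 2)) \
        if ends and starts else []
    # merge greedily following the assignment; chain merges are resolved
    merged_into = {}
    for a, b in links:
        i, j = ends[a][0], starts[b][0]
        merged_into[j] = i
    out = []
    consumed = set(merged_into)
    for i, tr in enumerate(tracks):
        if i in consumed:
            continue
        chain = list(tr)
        k = i
        # follow forward merges
        inverse = {v: k_ for k_, v in merged_into.items()}
        while k in inverse:
            k = inverse[k]
            chain.extend(tracks[k])
        out.append(chain)
    return out


def assign_status(track: AdhesionTrack,
                  segmentations: list[list[AdhesionRegion]],
                  shape: tuple[int, int]) -> list[str]:
    """Per-frame maturation status of a track against FC/FA segmentations.

    A point inside an FA-class region is ``FA``, inside an FC-class region
    ``FC``, otherwise ``NA`` (below_FC regions do not confer maturity).
    ``segmentations`` must cover every frame of the track.
    """
    maps = {}
    statuses = []
    for frame, x, y, _ in track.points:
        if frame >= len(segmentations):
            raise ValueError(f"no segmentation for frame {frame}")
        if frame not in maps:
            maps[frame] = class_map(segmentations[frame], shape)
        r = int(round(y))
        c = int(round(x))
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            statuses.append(NA)
            continue
        code = maps[frame][r, c]
        statuses.append(FA if code == 3 else FC if code == 2 else NA)
    track.status_sequence = statuses
    return statuses


@dataclass
class LifetimeSummary:
    na_lifetimes: list[float]
    fa_lifetimes: list[float]
    n_left_censored: int
    n_right_censored: int


def compute_lifetimes(tracks: list[AdhesionTrack], frame_interval: float,
                      frame_count: int | None = None) -> LifetimeSummary:
    """NA and FC/FA lifetimes in seconds.

    NA lifetimes come from tracks that never overlap an FC/FA region;
    FC/FA lifetimes from tracks containing FC or FA status at any time.
    Tracks alive at the movie start (frame 0) or end are censored and
    excluded from the returned lists. Lifetime convention: number of
    frames spanned × frame interval.
    """
    na, fafc = [], []
    left = right = 0
    for tr in tracks:
        if not tr.status_sequence:
            raise ValueError("assign_status must run before compute_lifetimes")
        censored = False
        if tr.first_frame == 0:
            left += 1
            censored = True
        if frame_count is not None and tr.last_frame >= frame_count - 1:
            right += 1
            censored = True
        if censored:
            continue
        life = tr.lifetime(frame_interval)
        if tr.matured:
            fafc.append(life)
        else:
            na.append(life)
    return LifetimeSummary(na, fafc, left, right)


def nucleation_and_maturation(tracks: list[AdhesionTrack],
                              min_frames: int = 3) -> dict:
    """Nucleation and maturation fractions over a track population.

    ``nucleating_fraction``: tracks first detected after frame 0 that
    persist ≥ ``min_frames`` frames, over all NA-containing tracks.
    ``maturing_fraction``: matured tracks over NA-born tracks (tracks whose
    first status is NA). A zero denominator yields ``None`` for that
    fraction (flagged, never a propagating NaN).
    """
    na_containing = [t for t in tracks if NA in t.status_sequence]
    nucleating = [t for t in na_containing
                  if t.first_frame > 0 and len(t.points) >= min_frames]
    na_born = [t for t in tracks
               if t.status_sequence and t.status_sequence[0] == NA]
    matured = [t for t in na_born if t.matured]
    return {
        "nucleating_fraction": (len(nucleating) / len(na_containing)
                                if na_containing else None),
        "maturing_fraction": (len(matured) / len(na_born)
                              if na_born else None),
        "n_tracks": len(tracks),
    }
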