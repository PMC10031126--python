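"""Filtering operators over the shared :class:`~sthcube.core.FilterState`.

One FilterState drives every view — the STC render, the voxel query and
any cross-section preview — so a filter applied anywhere is reflected
everywhere.  The three operators mirror the interactive tools of the
visualization:

* value filter — keep only instances whose mapped annotation value lies in
  a range (instances with a *missing* value are kept and show the sentinel
  color; dropping them would silently hide unannotated cells);
* time filter — keep only a window of time slices;
* object filter and tracking — highlight or hide an object; the state
  change propagates to every temporal instance of the id and to all its
  lineage descendants, which is what makes a whole sub-lineage trackable
  from a single click.

Filters never modify the stored STC; they are materialized on demand as a
boolean keep-mask by :func:`apply_filters` and applied at render/query
time.
"""

from __future__ import annotations

import numpy as np

from .core import (
    OBJECT_STATES,
    FilterState,
    LineageTree,
    ValidationError,
    propagate_selection,
)
from .projection import STCVolume
from typing import TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .volume_shading import ValueLookup

_CYCLE = {"normal": "highlighted", "highlighted": "hidden", "hidden": "normal"}


def value_filter(state: FilterState, lookup: "ValueLookup", lo: float, hi: float) -> FilterState:
    """Restrict the display to instances whose mapped value lies in [lo, hi].

    Suppression is decided per (id, t) instance on the property currently
    carried by ``lookup``; the range is stored on the state and evaluated
    by :func:`apply_filters`.
    """
    if lo > hi:
        raise ValidationError(f"value filter lo {lo} > hi {hi}")
    return state.with_(value_range=(float(lo), float(hi)))


def time_filter(state: FilterState, t0: int, t1: int, n_times: int | None = None) -> FilterState:
    """Restrict the display to time slices t0..t1 (inclusive).

    The preview time cursor is clamped into the window.  When ``n_times``
    is given the window is validated against it.
    """
    t0, t1 = int(t0), int(t1)
    if not 0 <= t0 <= t1:
        raise ValidationError(f"invalid time window [{t0}, {t1}]")
    if n_times is not None and t1 > n_times - 1:
        raise ValidationError(f"time window [{t0}, {t1}] exceeds last frame {n_times - 1}")
    cur = min(max(state.current_time, t0), t1)
    return state.with_(time_window=(t0, t1), current_time=cur)


def set_object_state(
    state: FilterState,
    lineage: LineageTree,
    seed: tuple[int, int],
    new_state: str,
) -> FilterState:
    """Set the highlight/hide state of an object and its whole sub-lineage.

    ``new_state`` is one of "normal", "highlighted", "hidden", or "next" —
    the interactive cycling order normal -> highlighted -> hidden ->
    normal, evaluated on the seed's current state.  The state is applied to
    every id in ``propagate_selection(lineage, seed)`` (the seed plus all
    descendants), across all their time instances.
    """
    if new_state == "next":
        new_state = _CYCLE[state.state_of(seed[0])]
    if new_state not in OBJECT_STATES:
        raise ValidationError(f"unknown object state {new_state!r}")
    ids = propagate_selection(lineage, seed)
    states = dict(state.object_states)
    for oid in ids:
        if new_state == "normal":
            states.pop(oid, None)
        else:
            states[oid] = new_state
    return state.with_(object_states=states)


def apply_filters(stc: STCVolume, lookup: "ValueLookup | None", state: FilterState) -> np.ndarray:
    """Materialize the FilterState as a boolean keep-mask over the STC.

    A voxel survives iff it is nonzero AND its slice is inside the time
    window AND its id is not hidden AND its mapped value (when defined and
    when a value range is set) lies inside the range.  Rendering a filtered
    volume is identical to rendering the pre-masked volume unfiltered.
    """
    if state is None:
        return stc.grid != 0
    mask = stc.grid != 0

    if state.time_window is not None:
        t0, t1 = state.time_window
        k = np.arange(stc.n_times)
        mask &= ((k >= t0) & (k <= t1))[None, None, :]

    hidden = state.hidden_ids()
    if hidden:
        mask &= ~np.isin(stc.grid, sorted(hidden))

    if state.value_range is not None and lookup is not None:
        lo, hi = state.value_range
        times = stc.times if stc.times else tuple(range(stc.n_times))
        for k, t in enumerate(times):
            ids = np.unique(stc.grid[:, :, k])
            bad = []
            for oid in ids:
                if oid == 0:
                    continue
                v = lookup.value(int(oid), int(t))
                if v is None:
                    continue  # missing values are kept (sentinel-rendered)
                try:
                    x = float(v)
                except (TypeError, ValueError):
                    continue  # categories are not range-filterable
                if not lo <= x <= hi:
                    bad.append(oid)
            if bad:
                mask[:, :, k] &= ~np.isin(stc.grid[:, :, k], bad)
    return mask
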