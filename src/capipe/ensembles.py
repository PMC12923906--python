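"""Cross-session ensemble recruitment and reactivation from the registration map.

A cell counts as active in a session when the longitudinal registration found
it there and it emitted at least ``min_active_events`` events (default 1).
Recruitment is expressed as a percentage of the habituation (reference)
ensemble; reactivation of a session pair is the percentage of the earlier
session's active cells that are active again in the later session.
"""

from __future__ import annotations

from typing import Mapping

import pandas as pd

from .core import SESSION_LABELS, EventTrain, RegistrationMap, ValidationError

DEFAULT_PAIRS = (("HA", "S1"), ("S1", "S2"), ("S2", "S3"))


def active_cells(
    regmap: RegistrationMap,
    session: str,
    events_by_session: Mapping[str, Mapping[str, EventTrain]] | None = None,
    min_active_events: int = 1,
) -> set:
    """Global ids active in ``session``.

    Without event data, presence in the registration column alone decides;
    with it, cells additionally need >= min_active_events events.
    """
    present = regmap.present(session)  # global id -> per-session index
    if events_by_session is None or session not in events_by_session:
        return set(present.index)
    events = events_by_session[session]
    out = set()
    for gid, idx in present.items():
        train = events.get(str(idx))
        if train is not None and train.n_events >= min_active_events:
            out.add(gid)
    return out


def active_percent(
    regmap: RegistrationMap,
    session: str,
    events_by_session: Mapping[str, Mapping[str, EventTrain]] | None = None,
    min_active_events: int = 1,
) -> float:
    """Active-cell count normalised to habituation, as a percentage.

    May exceed 100 when a later session recruits more cells than HA.
    """
    ha = active_cells(regmap, "HA", events_by_session, min_active_events)
    if not ha:
        raise ValidationError("habituation session has no active cells")
    current = active_cells(regmap, session, events_by_session, min_active_events)
    return 100.0 * len(current) / len(ha)


def reactivation_percent(
    regmap: RegistrationMap,
    earlier_session: str,
    later_session: str,
    events_by_session: Mapping[str, Mapping[str, EventTrain]] | None = None,
    min_active_events: int = 1,
) -> float:
    """Percentage of the earlier session's active cells re-active later."""
    earlier = active_cells(regmap, earlier_session, events_by_session, min_active_events)
    if not earlier:
        raise ValidationError(f"no active cells in {earlier_session}")
    later = active_cells(regmap, later_session, events_by_session, min_active_events)
    return 100.0 * len(earlier & later) / len(earlier)


def ensemble_table(
    regmap: RegistrationMap,
    animal_id: str,
    events_by_session: Mapping[str, Mapping[str, EventTrain]] | None = None,
    min_active_events: int = 1,
    pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
) -> pd.DataFrame:
    """Tidy table of per-session recruitment and per-pair reactivation."""
    rows = []
    for session in SESSION_LABELS:
        n = len(active_cells(regmap, session, events_by_session, min_active_events))
        rows.append(
            {"animal_id": animal_id, "session": session, "metric": "active_count", "value": n}
        )
        rows.append(
            {
                "animal_id": animal_id,
                "session": session,
                "metric": "active_percent_of_HA",
                "value": active_percent(regmap, session, events_by_session, min_active_events),
            }
        )
    for earlier, later in pairs:
        rows.append(
            {
                "animal_id": animal_id,
                "session": f"{earlier}->{later}",
                "metric": "reactivation_percent",
                "value": reactivation_percent(
                    regmap, earlier, later, events_by_session, min_active_events
                ),
            }
        )
    return pd.DataFrame(rows)
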