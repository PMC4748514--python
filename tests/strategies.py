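"""Hypothesis strategies for randomized session records.

Strings used as metric values avoid lexical forms that the compat parser
reinterprets (numbers, true/false), since datatype inference on plain
literals is part of the I/O contract.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

from hypothesis import strategies as st

from exergame import Iri, MetricObservation, SessionRecord, define_metric

_RESOURCES = "http://example.org/resources/"

_ID_ALPHABET = "abcdefghijklmnop0123456789_"

session_ids = st.text(alphabet=_ID_ALPHABET, min_size=1, max_size=12)

_metric_names = st.sampled_from(
    ["Success", "ReactionTime", "GoalTime", "TotalTime", "Score", "HeartRate"]
)

def _not_number_like(s: str) -> bool:
    try:
        float(s)
    except ValueError:
        return True
    return False


_safe_strings = (
    st.text(alphabet="abcdefghijklmnopqrstuvwxyz ", min_size=1, max_size=10)
    .map(str.strip)
    .filter(lambda s: s and s.lower() not in ("true", "false") and _not_number_like(s))
)

_value_lists = st.one_of(
    st.lists(st.booleans(), min_size=1, max_size=6),
    st.lists(st.integers(-10**6, 10**6), min_size=1, max_size=6),
    st.lists(
        st.floats(allow_nan=False, allow_infinity=False, width=32), min_size=1, max_size=6
    ),
    st.lists(_safe_strings, min_size=1, max_size=6),
)


@st.composite
def observations(draw, metric_name=None):
    name = metric_name or draw(_metric_names)
    metric = define_metric(name, name.lower())
    values = tuple(draw(_value_lists))
    unit = draw(
        st.one_of(st.none(), st.just(Iri("http://qudt.org/vocab/unit#SecondTime")))
    )
    return MetricObservation(metric=metric.iri, values=values, unit=unit)


@st.composite
def sessions(draw):
    names = draw(
        st.lists(_metric_names, min_size=1, max_size=4, unique=True)
    )
    obs = tuple(draw(observations(metric_name=n)) for n in names)
    start = draw(
        st.datetimes(
            min_value=datetime(2014, 1, 1),
            max_value=datetime(2016, 1, 1),
            timezones=st.sampled_from(
                [timezone.utc, timezone(timedelta(hours=2)), timezone(timedelta(hours=-5))]
            ),
        )
    )
    duration = draw(st.integers(0, 3600))
    site = draw(st.one_of(st.none(), st.just(Iri(_RESOURCES + "LivingLab"))))
    player_n = draw(st.integers(1, 20))
    game = draw(st.sampled_from(["SideRaisesGame", "AppleGame", "GolfGame"]))
    return SessionRecord(
        session_id=draw(session_ids),
        game=Iri(_RESOURCES + game),
        player=Iri(f"{_RESOURCES}player{player_n:03d}"),
        site=site,
        start=start,
        end=start + timedelta(seconds=duration),
        observations=obs,
    )
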