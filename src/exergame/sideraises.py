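"""Worked example: the "SideRaises" exergame and one recorded session.

SideRaises is a strength game for the upper limbs: the player holds hand
weights at their sides, raises both arms to shoulder height, holds, and
lowers them -- one iteration per raise.  It records three metrics per
iteration (success, reaction time, goal time), is driven by a Kinect
motion controller and presented on a smart TV, and its exercise involves
the deltoid, infraspinatus, teres minor, teres major and latissimus dorsi
muscles.

The session returned here is the published worked example from the
living-lab deployment: player ``player162`` at the Medical Physics
Laboratory (AUTh) on 2014-09-22, six iterations with Success values
TRUE, TRUE, FALSE, TRUE, FALSE, TRUE.  Only the Success values of that
session were published; the ReactionTime and GoalTime observations below
are synthetic stand-in values (fixed, plausible seconds) so the session
exercises all three metric relations.
"""

from __future__ import annotations

from datetime import datetime, timedelta, timezone

from .namespaces import CONCEPT_NS, CONTROLLER_NS, NCI_NS, OPE_NS, QUDT_UNIT_NS, Iri
from .records import (
    ControllerDefinition,
    ExerciseDefinition,
    GameDescription,
    Goal,
    HardwareRef,
    MetricObservation,
    MuscleRef,
    PlayerRecord,
    SessionRecord,
    SiteRecord,
    define_metric,
)

__all__ = ["sideraises_game", "sideraises_session", "sideraises_fixture", "RESOURCES_BASE"]

#: Resource base of the deployment that published the worked example.
RESOURCES_BASE = "http://www.fitforall.gr/resources/"

SECOND = Iri(QUDT_UNIT_NS + "SecondTime")
TIME_CONCEPT = Iri(CONCEPT_NS + "Time")

_SESSION_TIME = datetime(2014, 9, 22, 18, 9, 39, tzinfo=timezone(timedelta(hours=2)))

# Stand-in per-iteration values for the two metrics whose published rows
# were elided (synthetic; see module docstring).
_REACTION_TIME_VALUES = (1.2, 0.9, 1.5, 1.1, 1.4, 1.0)
_GOAL_TIME_VALUES = (4.1, 3.8, 5.0, 4.4, 4.9, 4.2)


def sideraises_game() -> GameDescription:
    """The SideRaises game description."""
    success = define_metric("Success", "success")
    reaction = define_metric("ReactionTime", "reaction time", concept=TIME_CONCEPT, unit=SECOND)
    goal_time = define_metric("GoalTime", "goal time", concept=TIME_CONCEPT, unit=SECOND)
    exercise = ExerciseDefinition(
        iri=Iri(RESOURCES_BASE + "SideRaisesExercise"),
        label="side raises",
        muscles=(
            MuscleRef(Iri(OPE_NS + "Deltoid"), source="ope"),
            MuscleRef(Iri(NCI_NS + "Infraspinatus"), source="ncit_subclass"),
            MuscleRef(Iri(NCI_NS + "Teres_Minor"), source="ncit_subclass"),
            MuscleRef(Iri(NCI_NS + "Teres_Major"), source="ncit_subclass"),
            MuscleRef(Iri(OPE_NS + "Latissimus_Dorsi"), source="ope"),
        ),
        equipment=("hand weights",),
        benefits=("upper limb strength",),
    )
    return GameDescription(
        iri=Iri(RESOURCES_BASE + "SideRaisesGame"),
        label="SideRaises",
        metrics=(success, reaction, goal_time),
        controllers=(
            ControllerDefinition(
                iri=Iri(CONTROLLER_NS + "Kinect"),
                label="Kinect",
                same_as=Iri("http://dbpedia.org/resource/Kinect"),
            ),
        ),
        presentation_hardware=(HardwareRef(Iri(RESOURCES_BASE + "SmartTV"), "smart TV"),),
        exercise=exercise,
        goals=(
            Goal("game_goal", "raise both arms to shoulder height in time"),
            Goal("exercise_goal", "proper execution of the side raise"),
        ),
    )


def sideraises_session() -> SessionRecord:
    """The worked-example session of SideRaises (see module docstring)."""
    game = sideraises_game()
    return SessionRecord(
        session_id="SideRaisesGameSession",
        game=game.iri,
        player=Iri(RESOURCES_BASE + "player162"),
        site=Iri(RESOURCES_BASE + "MedicalPhysicsLaboratoryAuth"),
        start=_SESSION_TIME,
        end=_SESSION_TIME,
        observations=(
            MetricObservation(
                metric=game.metric("Success").iri,
                values=(True, True, False, True, False, True),
            ),
            MetricObservation(
                metric=game.metric("ReactionTime").iri,
                values=_REACTION_TIME_VALUES,
                unit=SECOND,
            ),
            MetricObservation(
                metric=game.metric("GoalTime").iri,
                values=_GOAL_TIME_VALUES,
                unit=SECOND,
            ),
        ),
    )


def sideraises_fixture() -> tuple[GameDescription, SessionRecord]:
    """The (game, session) pair of the worked example; deterministic."""
    return sideraises_game(), sideraises_session()


def sideraises_site() -> SiteRecord:
    from .namespaces import SITETYPE_NS

    return SiteRecord(
        iri=Iri(RESOURCES_BASE + "MedicalPhysicsLaboratoryAuth"),
        site_type=Iri(SITETYPE_NS + "ResearchLaboratory"),
    )


def sideraises_player() -> PlayerRecord:
    return PlayerRecord(iri=Iri(RESOURCES_BASE + "player162"))
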