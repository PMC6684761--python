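"""Canonical sagittal-plane muscle catalogue for one leg.

Fifteen flexor/extensor muscle groups actuate the hip, knee and ankle in
the sagittal plane. Each muscle is classified by the joints it spans and
the sign of the joint torque it produces under the package convention
(hip flexion +, knee flexion +, ankle dorsiflexion +).

The default physiological constants (maximum isometric force, optimal
fiber length, ...) are generic adult lower-limb model values; they are
meant to be overridden per subject through a YAML parameter file (see
:func:`load_muscle_params`).
"""

from __future__ import annotations

from typing import Mapping

from .errors import SchemaError

JOINTS: tuple[str, ...] = ("hip", "knee", "ankle")

MUSCLES: tuple[str, ...] = (
    "rectus_femoris",
    "gluteus_maximus_1",
    "gluteus_maximus_2",
    "gluteus_maximus_3",
    "adductor_magnus",
    "semitendinosus",
    "semimembranosus",
    "biceps_femoris_long",
    "biceps_femoris_short",
    "vastus_lateralis",
    "vastus_medialis",
    "gastrocnemius_medial",
    "gastrocnemius_lateral",
    "tibialis_anterior",
    "tibialis_posterior",
)

# Signed anatomical action per spanned joint: +1 adds positive joint torque
# (flexion / flexion / dorsiflexion), -1 the antagonist action. Joints not
# listed are not spanned and carry an identically zero moment arm.
#
# Note: the short head of biceps femoris is carried here as a hip extensor +
# knee flexor, following the hamstring-group classification used by the
# torque-distribution model (see docs/methods.md for the anatomical caveat).
ACTIONS: Mapping[str, Mapping[str, int]] = {
    "rectus_femoris": {"hip": +1, "knee": -1},
    "gluteus_maximus_1": {"hip": -1},
    "gluteus_maximus_2": {"hip": -1},
    "gluteus_maximus_3": {"hip": -1},
    "adductor_magnus": {"hip": -1},
    "semitendinosus": {"hip": -1, "knee": +1},
    "semimembranosus": {"hip": -1, "knee": +1},
    "biceps_femoris_long": {"hip": -1, "knee": +1},
    "biceps_femoris_short": {"hip": -1, "knee": +1},
    "vastus_lateralis": {"knee": -1},
    "vastus_medialis": {"knee": -1},
    "gastrocnemius_medial": {"knee": +1, "ankle": -1},
    "gastrocnemius_lateral": {"knee": +1, "ankle": -1},
    "tibialis_anterior": {"ankle": +1},
    "tibialis_posterior": {"ankle": -1},
}

# Nominal (constant-term) moment-arm magnitudes in metres, per spanned
# joint. Values sit inside anatomical literature ranges for adult legs.
NOMINAL_MOMENT_ARMS: Mapping[str, Mapping[str, float]] = {
    "rectus_femoris": {"hip": 0.045, "knee": 0.045},
    "gluteus_maximus_1": {"hip": 0.055},
    "gluteus_maximus_2": {"hip": 0.060},
    "gluteus_maximus_3": {"hip": 0.050},
    "adductor_magnus": {"hip": 0.055},
    "semitendinosus": {"hip": 0.060, "knee": 0.035},
    "semimembranosus": {"hip": 0.055, "knee": 0.035},
    "biceps_femoris_long": {"hip": 0.055, "knee": 0.030},
    "biceps_femoris_short": {"hip": 0.020, "knee": 0.025},
    "vastus_lateralis": {"knee": 0.045},
    "vastus_medialis": {"knee": 0.045},
    "gastrocnemius_medial": {"knee": 0.020, "ankle": 0.050},
    "gastrocnemius_lateral": {"knee": 0.020, "ankle": 0.050},
    "tibialis_anterior": {"ankle": 0.040},
    "tibialis_posterior": {"ankle": 0.015},
}

# (max isometric force N, optimal fiber length m) — generic adult values.
_DEFAULT_F0_L0: Mapping[str, tuple[float, float]] = {
    "rectus_femoris": (780.0, 0.084),
    "gluteus_maximus_1": (570.0, 0.142),
    "gluteus_maximus_2": (550.0, 0.147),
    "gluteus_maximus_3": (550.0, 0.144),
    "adductor_magnus": (1000.0, 0.131),
    "semitendinosus": (330.0, 0.201),
    "semimembranosus": (1030.0, 0.080),
    "biceps_femoris_long": (720.0, 0.109),
    "biceps_femoris_short": (400.0, 0.173),
    "vastus_lateralis": (1870.0, 0.084),
    "vastus_medialis": (1290.0, 0.089),
    "gastrocnemius_medial": (1115.0, 0.060),
    "gastrocnemius_lateral": (490.0, 0.064),
    "tibialis_anterior": (600.0, 0.098),
    "tibialis_posterior": (1270.0, 0.031),
}


def spanned_joints(muscle: str) -> tuple[str, ...]:
    """Joints a muscle spans, in canonical (hip, knee, ankle) order."""
    if muscle not in ACTIONS:
        raise SchemaError(f"unknown muscle name: {muscle!r}")
    return tuple(j for j in JOINTS if j in ACTIONS[muscle])


def default_muscle_params() -> list:
    """Default :class:`~coact.muscle_model.MuscleParams` for the catalogue."""
    from .muscle_model import MuscleParams

    return [
        MuscleParams(name=m, f0=_DEFAULT_F0_L0[m][0], l0=_DEFAULT_F0_L0[m][1])
        for m in MUSCLES
    ]


_PARAM_FIELDS = {
    "f0", "l0", "vmax", "fl_width", "fv_shape", "fv_ecc_max",
    "passive_strain", "passive_exponent", "T_rise", "T_fall", "T_e",
}


def load_muscle_params(path) -> list:
    """Load per-muscle parameter overrides from a YAML file.

    The file maps canonical muscle names to ``MuscleParams`` field
    overrides; muscles that are absent keep their defaults. Unknown
    muscle names or fields raise :class:`~coact.errors.SchemaError`.
    """
    import yaml

    from .muscle_model import MuscleParams

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    if not isinstance(doc, dict):
        raise SchemaError("muscle parameter file must map muscle -> fields")
    params = {p.name: p for p in default_muscle_params()}
    for name, fields in doc.items():
        if name not in params:
            raise SchemaError(f"unknown muscle name in parameter file: {name!r}")
        if not isinstance(fields, dict):
            raise SchemaError(f"fields for {name!r} must be a mapping")
        bad = set(fields) - _PARAM_FIELDS
        if bad:
            raise SchemaError(
                f"unknown MuscleParams field(s) for {name!r}: {sorted(bad)}")
        merged = {**params[name].__dict__, **fields}
        params[name] = MuscleParams(**merged)
    return [params[m] for m in MUSCLES]
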