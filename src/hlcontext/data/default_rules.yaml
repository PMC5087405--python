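# Default high-level context class definitions.
#
# This ruleset is a reconstruction: only some cells of the original class
# scheme are documented in text, the rest are plausible defaults.
# Text-anchored cells:
#   OfficeWork   activity req {sitting}, location req {office},
#                emotion opt {anger, boredom, disgust, happiness, neutral}
#   Sleeping     {lying_down} @ {home}, emotion opt {neutral}
#   Amusement    requires emotion {happiness} (sitting-in-mall example)
#   Exercising   covers {running, climbing_stairs} @ {gym} with neutral
#   Inactivity   sedentary activity, location and emotion unconstrained
# The remaining cells are documented defaults chosen to be behaviorally
# plausible; override any of them by passing your own config.
#
# Schema: classes.<Name>.{activity|location|emotion}.{required: bool,
# allowed: [terms] | "any"}; "any" expands to the category vocabulary.
# A class with "enabled: false" is kept in the terminology but never matched.
# "priority" resolves multi-membership to a single reported label
# (specific-before-general).

classes:
  OfficeWork:
    activity: {required: true, allowed: [sitting]}
    location: {required: true, allowed: [office]}
    emotion: {required: false, allowed: [anger, boredom, disgust, happiness, neutral]}
  Sleeping:
    activity: {required: true, allowed: [lying_down]}
    location: {required: true, allowed: [home]}
    emotion: {required: false, allowed: [neutral]}
  HouseWork:
    activity: {required: true, allowed: [sweeping]}
    location: {required: true, allowed: [home]}
    emotion: {required: false, allowed: any}
  Commuting:
    activity: {required: true, allowed: [sitting, standing, walking, riding_escalator, riding_elevator]}
    location: {required: true, allowed: [transport]}
    emotion: {required: false, allowed: any}
  Amusement:
    activity: {required: true, allowed: [sitting, standing, walking, dancing]}
    location: {required: true, allowed: [mall]}
    emotion: {required: true, allowed: [happiness]}
  Gardening:
    activity: {required: true, allowed: [sweeping, walking, standing]}
    location: {required: true, allowed: [yard]}
    emotion: {required: false, allowed: any}
  Exercising:
    activity: {required: true, allowed: [running, jumping, hiking, climbing_stairs, descending_stairs, cycling, stretching, dancing]}
    location: {required: true, allowed: [gym, outdoors]}
    emotion: {required: false, allowed: [neutral, happiness]}
  HavingMeal:
    activity: {required: true, allowed: [eating]}
    location: {required: true, allowed: [home, restaurant]}
    emotion: {required: false, allowed: any}
  Inactivity:
    activity: {required: true, allowed: [sitting, lying_down]}
    location: {required: false, allowed: any}
    emotion: {required: false, allowed: any}
  NoHLC:
    enabled: false
    activity: {required: false, allowed: any}
    location: {required: false, allowed: any}
    emotion: {required: false, allowed: any}

priority:
  - Sleeping
  - Amusement
  - OfficeWork
  - HavingMeal
  - HouseWork
  - Gardening
  - Commuting
  - Exercising
  - Inactivity
  - NoHLC
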