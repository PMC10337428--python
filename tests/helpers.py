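"""Shared builders for test patients."""

from lifetriage.scores import Injury, VitalSigns, score_patient


def vitals(gcs=15, sbp=120, rr=16, **kw):
    defaults = dict(
        gcs_total=gcs,
        sbp=sbp,
        rr=rr,
        walking=kw.pop("walking", True),
        radial_pulse_palpable=kw.pop("radial_pulse_palpable", sbp >= 80),
        cap_refill_s=kw.pop("cap_refill_s", 1.0),
        obeys_commands=kw.pop("obeys_commands", gcs >= 13),
        breathing_after_airway_maneuver=kw.pop("breathing", rr > 0),
    )
    if defaults["rr"] == 0:
        defaults["walking"] = False
    defaults.update(kw)
    return VitalSigns(**defaults)


def injuries_from_ais(severities):
    return [
        Injury(trauma_type="fracture", body_location="left_arm", ais=a)
        for a in severities
    ]


def patient(pid, severities, **vital_kw):
    return score_patient(pid, injuries_from_ais(severities), vitals(**vital_kw))
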