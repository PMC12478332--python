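"""Canonical manifold geometries, drug roster and scenario fixtures.

Two envelopes are bundled, matching typical critical-care conditions:

* ``adult``      — carrier 10 mL/h, most-distal-port dead volume 1.2 mL
* ``pediatric``  — carrier 1.5 mL/h, most-distal-port dead volume 0.7 mL

Each is a chain of four stopcock units feeding a single catheter lumen.
Published assemblies report only the aggregate dead volume, so the
catheter radius is solved here so that the most distal port's dead
volume matches the envelope exactly; the per-segment split is a free
calibration recorded in the generated scenario files.
"""

from __future__ import annotations

import numpy as np

from .manifold import ManifoldSpec, PortMap, SegmentSpec, build_manifold
from .transport import DrugSpec

__all__ = [
    "manifold_fixture",
    "default_drug",
    "DRUG_TABLE",
    "adult_single_drug",
    "pediatric_single_drug",
    "pediatric_two_drug",
]

#: (envelope) -> (stopcock length mm, stopcock radius mm, catheter length mm,
#:               target dead volume mL, carrier mL/h)
_GEOM = {
    "adult": (25.0, 1.5, 500.0, 1.2, 10.0),
    "pediatric": (20.0, 1.2, 400.0, 0.7, 1.5),
}

#: therapeutic action timescales (s).  ``literature`` entries have published
#: values (propofol-like 40 s); the rest are representative
#: order-of-magnitude values for the drug class.
DRUG_TABLE: dict[str, dict] = {
    "propofol":       {"tau_a_s": 40.0,   "source": "literature"},
    "phenylephrine":  {"tau_a_s": 60.0,   "source": "representative"},
    "norepinephrine": {"tau_a_s": 60.0,   "source": "representative"},
    "clevidipine":    {"tau_a_s": 90.0,   "source": "representative"},
    "ketamine":       {"tau_a_s": 120.0,  "source": "representative"},
    "nitroglycerin":  {"tau_a_s": 120.0,  "source": "representative"},
    "amiodarone":     {"tau_a_s": 7200.0, "source": "representative"},
    "furosemide":     {"tau_a_s": 3600.0, "source": "representative"},
}


def manifold_fixture(kind: str = "adult") -> ManifoldSpec:
    """Four-stopcock + catheter manifold with calibrated dead volume.

    Port 4 sits at the manifold entrance (most distal from the tip), so
    its dead volume equals the whole internal volume — 1.2 mL (adult) or
    0.7 mL (pediatric).  Ports 3..1 sit at successive stopcock junctions.
    """
    try:
        sl, sr, cl, vdead_ml, _ = _GEOM[kind]
    except KeyError:
        raise ValueError(f"unknown fixture kind {kind!r}; expected adult|pediatric")
    stop_vol = 4 * np.pi * sr**2 * sl
    cath_area = (vdead_ml * 1000.0 - stop_vol) / cl
    cath_radius = float(np.sqrt(cath_area / np.pi))
    segments = [SegmentSpec(sl, sr, f"stopcock_{i}") for i in range(4, 0, -1)]
    segments.append(SegmentSpec(cl, cath_radius, "catheter"))
    ports = PortMap({4: 0.0, 3: sl, 2: 2 * sl, 1: 3 * sl})
    return build_manifold(segments, ports)


def carrier_rate(kind: str) -> float:
    return _GEOM[kind][4]


def default_drug(name: str = "propofol", syringe_conc: float = 1.0) -> DrugSpec:
    tau = DRUG_TABLE.get(name, {"tau_a_s": 60.0})["tau_a_s"]
    return DrugSpec(name=name, syringe_conc=syringe_conc, diffusivity_m2s=5e-10, tau_a_s=tau)


def adult_single_drug(drug_rate_mlh: float = 1.0, port: int = 4):
    """Adult envelope, one drug at the most distal port (default)."""
    man = manifold_fixture("adult")
    drugs = {port: default_drug("propofol")}
    return man, drugs, (carrier_rate("adult"), {port: drug_rate_mlh})


def pediatric_single_drug(drug_rate_mlh: float = 0.5, port: int = 4):
    man = manifold_fixture("pediatric")
    drugs = {port: default_drug("propofol")}
    return man, drugs, (carrier_rate("pediatric"), {port: drug_rate_mlh})


def pediatric_two_drug(rate1: float = 0.5, rate2: float = 0.5):
    """Two drugs on the pediatric envelope: drug 1 at port 4, drug 2 at port 3."""
    man = manifold_fixture("pediatric")
    drugs = {4: default_drug("phenylephrine"), 3: default_drug("norepinephrine")}
    return man, drugs, (carrier_rate("pediatric"), {4: rate1, 3: rate2})
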