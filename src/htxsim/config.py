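"""Cohort parameter sets and their YAML serialization.

A :class:`CohortConfig` carries the complete parameter state of one
simulated cohort: the packed circulation, SA-cell and controller vectors
plus demographic scalars.  Every named parameter carries a provenance tag:

* ``paper``       -- value printed in the source publication
* ``cited-model`` -- taken from established source models (Ursino-school
                     controller constants, standard physiologic values)
* ``calibrated``  -- free parameter tuned so the closed-loop cohort
                     hemodynamics match the pooled clinical targets
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import autonomic as au
from . import hemodynamics as hd
from . import sa_node as sn

__all__ = ["CohortConfig", "param_names", "load_config", "save_config"]


def _index_names(module, size: int, skip=()) -> list:
    """Recover ordered parameter names from a module's index constants."""
    names = [None] * size
    for key, val in vars(module).items():
        if (
            key.isupper()
            and isinstance(val, int)
            and not key.startswith("N")
            and key not in skip
            and 0 <= val < size
        ):
            if names[val] is None:
                names[val] = key
    return [n if n is not None else f"p{i}" for i, n in enumerate(names)]


_SKIP_HD = {
    "NCV", "NCVP", "NAUX_CV",
    "IV_LA", "IV_LV", "IV_RA", "IV_RV", "IV_AO", "IV_SV", "IV_PA", "IV_PV",
}
SA_NAMES = _index_names(sn, sn.NSAP, skip={"NSA", "NSAP"})
CV_NAMES = _index_names(hd, hd.NCVP, skip=_SKIP_HD)
CT_NAMES = _index_names(au, au.NCTP, skip={"NCTP"})

_UNITS = {
    # circulation
    "LV_EMAX": "mmHg/mL", "LV_EMIN": "mmHg/mL", "LV_VU": "mL",
    "LV_A": "mmHg", "LV_B": "1/mL",
    "RV_EMAX": "mmHg/mL", "RV_EMIN": "mmHg/mL", "RV_VU": "mL",
    "RV_A": "mmHg", "RV_B": "1/mL",
    "LA_EMAX": "mmHg/mL", "LA_EMIN": "mmHg/mL", "LA_VU": "mL",
    "RA_EMAX": "mmHg/mL", "RA_EMIN": "mmHg/mL", "RA_VU": "mL",
    "R_MV": "mmHg.s/mL", "R_AV": "mmHg.s/mL", "R_TV": "mmHg.s/mL",
    "R_PVALVE": "mmHg.s/mL",
    "C_AO": "mL/mmHg", "VU_AO": "mL", "C_SV": "mL/mmHg", "R_VR": "mmHg.s/mL",
    "C_PA": "mL/mmHg", "VU_PA": "mL", "R_PA": "mmHg.s/mL",
    "C_PV": "mL/mmHg", "VU_PV": "mL", "R_PVN": "mmHg.s/mL",
    "AV_DELAY0": "s", "TSYS0": "s", "TAS0": "s", "RR_REF": "s",
    "PIT0": "mmHg", "PIT_AMP": "mmHg", "PABD0": "mmHg", "PABD_AMP": "mmHg",
    "FRC": "L", "VT_REST": "L", "VT_SLOPE": "L",
    "TRESP_REST": "s", "TRESP_PEAK": "s",
    # controller
    "P_SET_BASAL": "mmHg", "K_AB": "mmHg", "TAU_PBAR": "s",
    "F_AB_MIN": "spikes/s", "F_AB_MAX": "spikes/s",
    "F_ES0": "spikes/s", "F_ES_INF": "spikes/s", "K_ES": "s",
    "F_ES_MIN": "spikes/s", "F_EV0": "spikes/s", "F_EV_INF": "spikes/s",
    "K_EV": "spikes/s", "F_AB_HALF": "spikes/s",
    "G_AP": "spikes/s/L", "F_AP_REF": "spikes/s",
    "TAU_E": "s", "G_R": "mmHg.s/mL", "TAU_R": "s", "R_AS0": "mmHg.s/mL",
    "G_VU": "mL", "TAU_VU": "s", "V_USV0": "mL",
    "TAU_ISO": "s", "TAU_ACH": "s", "TAU_ADR": "s", "TAU_MET": "s",
    # SA cell
    "E_F": "mV", "E_CA": "mV", "E_K": "mV", "E_B": "mV",
    "VY_HALF": "mV", "K_Y": "mV", "VD_HALF": "mV", "K_D": "mV",
    "VF_HALF": "mV", "K_FG": "mV", "VN_HALF": "mV", "K_N": "mV",
    "TAU_Y0": "s", "TAU_Y_AMP": "s", "TAU_D": "s", "TAU_F": "s",
    "TAU_N0": "s", "TAU_N_AMP": "s", "TAU_CA": "s",
    "G_F": "1/s", "G_CAL": "1/s", "G_K": "1/s", "G_KACH": "1/s", "G_B": "1/s",
    "I_NAK": "mV/s", "CA_REST": "mM", "K_FCA": "mM", "K_CA_IN": "mM/mV",
    "S_ISO": "mV", "S_ACH": "mV", "D_SHIFT_ISO": "mV", "D_SHIFT_ACH": "mV",
}


def param_names():
    """(section -> ordered parameter-name list) for the packed vectors."""
    return {"sa_node": SA_NAMES, "circulation": CV_NAMES, "control": CT_NAMES}


@dataclass
class CohortConfig:
    """Complete parameter set of one simulated cohort."""

    label: str                      # "healthy" | "htxr"
    bsa: float                      # body surface area, m^2
    mtp: float                      # maximum tolerated power, kpm/min
    peak_intensity: float           # protocol endpoint, fraction of healthy MTP
    sa: np.ndarray = field(default_factory=sn.default_sa_params)
    cv: np.ndarray = field(default_factory=hd.default_cv_params)
    control: np.ndarray = field(default_factory=au.default_control_params)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.bsa <= 0 or self.mtp <= 0:
            raise ValueError("BSA and MTP must be > 0")
        self.sa = np.asarray(self.sa, dtype=float)
        self.cv = np.asarray(self.cv, dtype=float)
        self.control = np.asarray(self.control, dtype=float)
        if self.sa.shape != (sn.NSAP,) or self.cv.shape != (hd.NCVP,) \
                or self.control.shape != (au.NCTP,):
            raise ValueError("packed parameter vector has wrong length")

    # convenient named access ------------------------------------------------
    @property
    def basal_ach(self) -> float:
        return float(self.control[au.BASAL_ACH])

    @basal_ach.setter
    def basal_ach(self, v: float):
        self.control[au.BASAL_ACH] = v

    @property
    def basal_iso(self) -> float:
        return float(self.control[au.BASAL_ISO])

    @basal_iso.setter
    def basal_iso(self, v: float):
        self.control[au.BASAL_ISO] = v

    def copy(self) -> "CohortConfig":
        return CohortConfig(
            self.label, self.bsa, self.mtp, self.peak_intensity,
            self.sa.copy(), self.cv.copy(), self.control.copy(),
            dict(self.provenance),
        )

    def validate(self):
        """Check structural invariants; raise ValueError listing gaps."""
        problems = []
        for sec, arr in (("sa_node", self.sa), ("circulation", self.cv),
                         ("control", self.control)):
            if not np.all(np.isfinite(arr)):
                problems.append(f"{sec}: non-finite parameter")
        for pfx in ("LV", "RV", "LA", "RA"):
            emax = self.cv[getattr(hd, pfx + "_EMAX")]
            emin = self.cv[getattr(hd, pfx + "_EMIN")]
            if not (emax >= emin > 0):
                problems.append(f"{pfx}: require E_max >= E_min > 0")
        for nm in ("R_MV", "R_AV", "R_TV", "R_PVALVE", "R_VR", "R_PA", "R_PVN"):
            if self.cv[getattr(hd, nm)] <= 0:
                problems.append(f"{nm} must be > 0")
        for nm in ("C_AO", "C_SV", "C_PA", "C_PV"):
            if self.cv[getattr(hd, nm)] <= 0:
                problems.append(f"{nm} must be > 0")
        if self.basal_ach < 0 or self.basal_iso < 0:
            problems.append("basal neurotransmitter concentrations must be >= 0")
        if problems:
            raise ValueError("invalid cohort config: " + "; ".join(problems))
        return self


def save_config(config: CohortConfig, path):
    """Write a cohort config as YAML with per-parameter provenance."""
    sections = {}
    for sec, names, arr in (
        ("sa_node", SA_NAMES, config.sa),
        ("circulation", CV_NAMES, config.cv),
        ("control", CT_NAMES, config.control),
    ):
        sections[sec] = {
            nm: {
                "value": float(arr[i]),
                "units": _UNITS.get(nm, "1"),
                "provenance": config.provenance.get(nm, "cited-model"),
            }
            for i, nm in enumerate(names)
        }
    doc = {
        "label": config.label,
        "bsa": {"value": config.bsa, "units": "m^2",
                "provenance": config.provenance.get("bsa", "calibrated")},
        "mtp": {"value": config.mtp, "units": "kpm/min",
                "provenance": config.provenance.get("mtp", "paper")},
        "peak_intensity": {"value": config.peak_intensity, "units": "1",
                           "provenance": "paper"},
        "parameters": sections,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_config(path) -> CohortConfig:
    """Read a cohort config written by :func:`save_config`."""
    doc = yaml.safe_load(Path(path).read_text())
    arrays = {}
    prov = {}
    for sec, names, size in (
        ("sa_node", SA_NAMES, sn.NSAP),
        ("circulation", CV_NAMES, hd.NCVP),
        ("control", CT_NAMES, au.NCTP),
    ):
        arr = np.zeros(size)
        entries = doc["parameters"][sec]
        missing = [nm for nm in names if nm not in entries]
        if missing:
            raise ValueError(f"config missing parameters in {sec}: {missing}")
        for i, nm in enumerate(names):
            arr[i] = float(entries[nm]["value"])
            prov[nm] = entries[nm].get("provenance", "cited-model")
        arrays[sec] = arr
    prov["bsa"] = doc["bsa"].get("provenance", "calibrated")
    prov["mtp"] = doc["mtp"].get("provenance", "paper")
    cfg = CohortConfig(
        label=doc["label"],
        bsa=float(doc["bsa"]["value"]),
        mtp=float(doc["mtp"]["value"]),
        peak_intensity=float(doc["peak_intensity"]["value"]),
        sa=arrays["sa_node"],
        cv=arrays["circulation"],
        control=arrays["control"],
        provenance=prov,
    )
    return cfg.validate()
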