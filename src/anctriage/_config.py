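"""Loading and validation of the threshold decision table and the
recommendation catalogue.

Both the rules engine and the independent validation oracle read the same
raw configuration; nothing else is shared between them.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

__all__ = [
    "ConfigError",
    "Thresholds",
    "load_raw_thresholds",
    "load_thresholds",
    "load_recommendations",
    "perturb_threshold",
    "band_edges",
]


class ConfigError(ValueError):
    """Raised when a threshold or catalogue file is missing required keys."""


_REQUIRED = {
    "bp": ("sbp_yellow", "sbp_red", "dbp_yellow", "dbp_red", "si_yellow", "si_red"),
    "hb": ("red_below", "referral_below", "yellow_below"),
    "ogtt": ("yellow_at", "red_at"),
    "units": ("sbp", "dbp", "heart_rate", "shock_index", "hb", "ogtt_2h_glucose"),
    "resolution": ("bp", "heart_rate", "si", "hb", "glucose"),
}

_REQUIRED_REC_CODES = ("HTN_SEVERE_URGENT",)


def _read_packaged(name: str) -> str:
    return (resources.files("anctriage") / "config" / name).read_text()


def load_raw_thresholds(path: str | Path | None = None) -> dict:
    """Load the threshold config as a plain nested dict, refusing to start
    if any required key is absent or band ordering is inconsistent."""
    if path is None:
        raw = yaml.safe_load(_read_packaged("thresholds.yaml"))
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("threshold config is not a mapping")
    for section, keys in _REQUIRED.items():
        if section not in raw:
            raise ConfigError(f"threshold config missing section {section!r}")
        for key in keys:
            if key not in raw[section]:
                raise ConfigError(f"threshold config missing key {section}.{key}")
    bp, hb, ogtt = raw["bp"], raw["hb"], raw["ogtt"]
    if not (bp["sbp_yellow"] < bp["sbp_red"]):
        raise ConfigError("bp.sbp_yellow must be below bp.sbp_red")
    if not (bp["dbp_yellow"] < bp["dbp_red"]):
        raise ConfigError("bp.dbp_yellow must be below bp.dbp_red")
    if not (bp["si_yellow"] < bp["si_red"]):
        raise ConfigError("bp.si_yellow must be below bp.si_red")
    if not (hb["red_below"] <= hb["referral_below"] <= hb["yellow_below"]):
        raise ConfigError("hb bands must satisfy red_below <= referral_below <= yellow_below")
    if not (ogtt["yellow_at"] < ogtt["red_at"]):
        raise ConfigError("ogtt.yellow_at must be below ogtt.red_at")
    return raw


@dataclass(frozen=True)
class Thresholds:
    """Typed view of the decision table used by the rules engine."""

    sbp_yellow: float
    sbp_red: float
    dbp_yellow: float
    dbp_red: float
    si_yellow: float
    si_red: float
    hb_red_below: float
    hb_referral_below: float
    hb_yellow_below: float
    ogtt_yellow_at: float
    ogtt_red_at: float

    @classmethod
    def from_raw(cls, raw: dict) -> "Thresholds":
        bp, hb, ogtt = raw["bp"], raw["hb"], raw["ogtt"]
        return cls(
            sbp_yellow=bp["sbp_yellow"],
            sbp_red=bp["sbp_red"],
            dbp_yellow=bp["dbp_yellow"],
            dbp_red=bp["dbp_red"],
            si_yellow=bp["si_yellow"],
            si_red=bp["si_red"],
            hb_red_below=hb["red_below"],
            hb_referral_below=hb["referral_below"],
            hb_yellow_below=hb["yellow_below"],
            ogtt_yellow_at=ogtt["yellow_at"],
            ogtt_red_at=ogtt["red_at"],
        )


def load_thresholds(path: str | Path | None = None) -> Thresholds:
    return Thresholds.from_raw(load_raw_thresholds(path))


def load_recommendations(path: str | Path | None = None) -> dict[str, str]:
    """Load the recommendation catalogue (code -> display text)."""
    if path is None:
        raw = yaml.safe_load(_read_packaged("recommendations.yaml"))
    else:
        raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("recommendation catalogue is not a mapping")
    for code in _REQUIRED_REC_CODES:
        if code not in raw:
            raise ConfigError(f"recommendation catalogue missing code {code!r}")
    return {str(k): str(v) for k, v in raw.items()}


def perturb_threshold(raw: dict, dotted_key: str, delta: float) -> dict:
    """Return a deep copy of ``raw`` with one band edge shifted by ``delta``.

    ``dotted_key`` is e.g. ``"bp.sbp_yellow"`` or ``"hb.referral_below"``.
    Used by mutation-sensitivity checks and the CLI's mutated-threshold mode.
    """
    section, _, key = dotted_key.partition(".")
    if section not in raw or key not in raw[section]:
        raise ConfigError(f"unknown threshold key {dotted_key!r}")
    mutated = copy.deepcopy(raw)
    # keep one-decimal edges exact in float (e.g. 10.0 - 0.1 -> 9.9)
    mutated[section][key] = round(raw[section][key] + delta, 6)
    return mutated


def band_edges(raw: dict) -> dict[str, tuple[str, float, float]]:
    """Map each mutable band edge to (measurement kind, value, resolution step).

    Keys are dotted, suitable for :func:`perturb_threshold`.
    """
    res = raw["resolution"]
    return {
        "bp.sbp_yellow": ("sbp", raw["bp"]["sbp_yellow"], res["bp"]),
        "bp.sbp_red": ("sbp", raw["bp"]["sbp_red"], res["bp"]),
        "bp.dbp_yellow": ("dbp", raw["bp"]["dbp_yellow"], res["bp"]),
        "bp.dbp_red": ("dbp", raw["bp"]["dbp_red"], res["bp"]),
        "bp.si_yellow": ("si", raw["bp"]["si_yellow"], res["si"]),
        "bp.si_red": ("si", raw["bp"]["si_red"], res["si"]),
        "hb.red_below": ("hb", raw["hb"]["red_below"], res["hb"]),
        "hb.referral_below": ("hb", raw["hb"]["referral_below"], res["hb"]),
        "hb.yellow_below": ("hb", raw["hb"]["yellow_below"], res["hb"]),
        "ogtt.yellow_at": ("glucose", raw["ogtt"]["yellow_at"], res["glucose"]),
        "ogtt.red_at": ("glucose", raw["ogtt"]["red_at"], res["glucose"]),
    }
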