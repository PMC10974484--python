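"""Clinical-test catalog: which parameters feed which test item.

The catalog binds each item of the supported fall-risk tests (Tinetti,
Berg, Dynamic Gait Index, TUG, FRT, FSST, SLS) to the minimum set of
measurable parameters relevant to it, and `evaluate_item` turns a skeleton
sequence into a per-item report: the parameter time series, their
summaries, and the applicable event detections (stride lengths, sit<->stand
transitions, arm-support flag).  Clinical scoring itself is left to the
therapist — the report is the objective evidence, not the score.

The mapping ships as a versioned YAML data file so clinicians can amend it
without touching code.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import parameters as par
from .errors import CatalogLookupError

TEST_IDS = ("tinetti", "berg", "dgi", "tug", "frt", "fsst", "sls")

#: Canonical catalog parameter vocabulary (the nine measurements).
PARAMETER_NAMES = frozenset({
    "speed", "trajectory", "trunk_swing", "separation_of_arms",
    "separation_of_heels", "stride", "trunk_tilt", "hand_separation",
    "arm_support",
})

_EXPECTED_ITEM_COUNTS = {"tinetti": 16, "berg": 14, "dgi": 8,
                         "tug": 1, "frt": 1, "fsst": 1, "sls": 1}


def default_catalog_path() -> Path:
    return Path(resources.files("gaitlab") / "data" / "catalog.yaml")


def load_catalog(path=None) -> dict:
    """Load and validate a catalog file; defaults to the shipped one."""
    path = Path(path) if path else default_catalog_path()
    raw = yaml.safe_load(path.read_text())
    catalog: dict = {}
    for test_id in TEST_IDS:
        if test_id not in raw:
            raise ValueError(f"catalog is missing test {test_id!r}")
        items = {}
        for row in raw[test_id]:
            params = frozenset(row["params"])
            if not params:
                raise ValueError(f"{test_id} item {row['item']}: empty params")
            unknown = params - PARAMETER_NAMES
            if unknown:
                raise ValueError(
                    f"{test_id} item {row['item']}: unknown {sorted(unknown)}")
            items[int(row["item"])] = params
        if sorted(items) != list(range(1, _EXPECTED_ITEM_COUNTS[test_id] + 1)):
            raise ValueError(f"{test_id}: items must be 1.."
                             f"{_EXPECTED_ITEM_COUNTS[test_id]}")
        catalog[test_id] = items
    return catalog


_default_catalog = None


def _catalog(catalog=None) -> dict:
    global _default_catalog
    if catalog is not None:
        return catalog
    if _default_catalog is None:
        _default_catalog = load_catalog()
    return _default_catalog


@dataclass(frozen=True)
class TestItem:
    """One catalog row: a test item and its parameter set."""

    test_id: str
    item_number: int
    parameters: frozenset


def parameters_for_item(test_id: str, item_number: int = 1,
                        catalog=None) -> frozenset:
    """The exact parameter set for one test item."""
    cat = _catalog(catalog)
    if test_id not in cat:
        raise CatalogLookupError(f"unknown test {test_id!r}")
    if item_number not in cat[test_id]:
        raise CatalogLookupError(
            f"{test_id} has no item {item_number}; valid: "
            f"{sorted(cat[test_id])}")
    return cat[test_id][item_number]


def list_items(test_id: str, catalog=None) -> list[TestItem]:
    """All items of a test, in catalog order."""
    cat = _catalog(catalog)
    if test_id not in cat:
        raise CatalogLookupError(f"unknown test {test_id!r}")
    return [TestItem(test_id, n, cat[test_id][n])
            for n in sorted(cat[test_id])]


@dataclass
class SessionReport:
    """Per-item evaluation: series, summaries, events, failures."""

    patient: str
    test_id: str
    item_number: int
    series: dict = field(default_factory=dict)      # name -> ParameterSeries
    trajectory: object = None                       # TrajectorySeries or None
    summaries: dict = field(default_factory=dict)   # name -> summary dict
    events: dict = field(default_factory=dict)      # detector outputs
    failures: dict = field(default_factory=dict)    # parameter -> error text

    def to_dict(self) -> dict:
        d = {"patient": self.patient, "test_id": self.test_id,
             "item_number": self.item_number,
             "series": {k: s.to_dict() for k, s in self.series.items()},
             "summaries": self.summaries, "events": self.events,
             "failures": self.failures}
        if self.trajectory is not None:
            d["trajectory"] = self.trajectory.to_dict()
        return d

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


# Which concrete series each catalog parameter expands to.
_SERIES_BUILDERS = {
    "speed": lambda seq: {"speed": par.speed_series(seq)},
    "trunk_swing": lambda seq: {"trunk_swing": par.trunk_swing(seq)},
    "separation_of_arms": lambda seq: {
        "arm_separation_left": par.arm_separation(seq, "left"),
        "arm_separation_right": par.arm_separation(seq, "right")},
    "separation_of_heels": lambda seq: {
        "heel_separation": par.heel_separation(seq)},
    "stride": lambda seq: {"stride": par.stride_signal(seq)},
    "trunk_tilt": lambda seq: {
        "trunk_tilt_left": par.trunk_tilt(seq, "left"),
        "trunk_tilt_right": par.trunk_tilt(seq, "right"),
        "trunk_tilt_mean": par.trunk_tilt_mean(seq)},
    "hand_separation": lambda seq: {
        "hand_separation": par.hand_separation(seq)},
    "arm_support": lambda seq: {
        "arm_support_left": par.arm_support_angle(seq, "left"),
        "arm_support_right": par.arm_support_angle(seq, "right")},
}


def evaluate_item(test_id: str, item_number: int, seq,
                  patient: str = "anonymous",
                  catalog=None) -> SessionReport:
    """Compute every series and event detector an item calls for.

    Individual parameter failures are recorded in ``report.failures``
    rather than aborting the whole report.
    """
    if not seq:
        raise ValueError("cannot evaluate an empty skeleton sequence")
    wanted = parameters_for_item(test_id, item_number, catalog)
    report = SessionReport(patient, test_id, item_number)
    for name in sorted(wanted):
        try:
            if name == "trajectory":
                report.trajectory = par.trajectory_series(seq)
                continue
            for key, series in _SERIES_BUILDERS[name](seq).items():
                report.series[key] = series
                report.summaries[key] = series.summary()
        except Exception as exc:  # per-series failure record
            report.failures[name] = f"{type(exc).__name__}: {exc}"
    # Event detectors applicable to the computed series.
    if "stride" in report.series:
        try:
            report.events["stride_lengths"] = [
                list(p) for p in
                par.detect_stride_lengths(report.series["stride"])]
        except Exception as exc:
            report.failures["stride_lengths"] = f"{type(exc).__name__}: {exc}"
    if "arm_support" in wanted:
        try:
            trunk = report.series.get("trunk_tilt_mean")
            if trunk is None:  # arm support needs the trunk signal too
                trunk = par.trunk_tilt_mean(seq)
            result = par.detect_arm_support(
                trunk, report.series["arm_support_left"],
                report.series["arm_support_right"])
            report.events["arm_support"] = {
                "used": result.used,
                "windows": [list(w) for w in result.windows],
                "min_angle": result.min_angle}
        except Exception as exc:
            report.failures["arm_support"] = f"{type(exc).__name__}: {exc}"
    return report
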