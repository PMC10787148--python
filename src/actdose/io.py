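"""Flat-file configuration and session-log serialization.

One human-readable ``key = value`` config document drives an entire
simulated trial (goal window, protocol parameters, population, manual
policy, arm sizes, seed) so any result can be reproduced from the file
plus a seed.  Unknown keys are an error: a typo must never silently fall
back to a default.

Session logs are line-delimited event records (one ACT draw, bolus or
infusion change per line) preceded by ``#``-prefixed metadata; writing and
re-reading a case round-trips it exactly, so the outcome extractors can be
re-run on archived logs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Optional

from .engine import (
    ANTICOAGULANTS,
    ActMeasurement,
    DoseEvent,
    GoalRange,
    ProtocolParams,
    ValidationError,
)
from .simulate import DrugPopulation, ManualPolicy, PopulationSpec
from .trial import CaseRecord


class ConfigError(ValueError):
    """A config document failed to parse or validate."""


class SessionFormatError(ValueError):
    """A session log is malformed; the message carries the line number."""


@dataclass
class RunConfig:
    """Everything needed to reproduce one simulated trial."""

    goal: GoalRange = field(default_factory=GoalRange)
    protocol: ProtocolParams = field(default_factory=ProtocolParams)
    population: PopulationSpec = field(default_factory=PopulationSpec)
    manual: ManualPolicy = field(default_factory=ManualPolicy)
    n_control: int = 50
    n_algo: int = 139
    duration: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 1 or self.n_algo < 1:
            raise ConfigError("arm sizes must be >= 1")
        if not self.duration > 0:
            raise ConfigError("duration must be > 0")


# ---------------------------------------------------------------------------
# Flat config dialect
# ---------------------------------------------------------------------------

_BOOL = {"true": True, "false": False}


def _fmt(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, float):
        if math.isinf(value):
            return "inf"
        return repr(value)
    return str(value)


def _parse(raw: str, typ):
    raw = raw.strip()
    if typ is bool:
        if raw not in _BOOL:
            raise ValueError(f"expected true/false, got {raw!r}")
        return _BOOL[raw]
    if typ is int:
        return int(raw)
    if typ is float:
        if raw == "inf":
            return math.inf
        return float(raw)
    return raw


def _schema() -> dict:
    """key -> (getter, setter-path, type).

    The schema is generated from the dataclasses so the config file and
    the in-memory parameter objects cannot drift apart.
    """
    schema = {}

    def add(key, typ, get, put):
        schema[key] = (typ, get, put)

    for name in ("low", "high", "center", "supra_threshold"):
        add(f"goal.{name}", float,
            lambda c, n=name: getattr(c.goal, n),
            lambda d, v, n=name: d["goal"].__setitem__(n, v))

    for drug in ANTICOAGULANTS:
        add(f"protocol.bolus_rate.{drug}", float,
            lambda c, d=drug: c.protocol.bolus_rates[d],
            lambda dd, v, d=drug: dd["bolus_rates"].__setitem__(d, v))
        add(f"protocol.infusion_rate.{drug}", float,
            lambda c, d=drug: c.protocol.infusion_rates[d],
            lambda dd, v, d=drug: dd["infusion_rates"].__setitem__(d, v))
    for f in fields(ProtocolParams):
        if f.name in ("bolus_rates", "infusion_rates"):
            continue
        typ = bool if f.type == "bool" else int if f.type == "int" else float
        add(f"protocol.{f.name}", typ,
            lambda c, n=f.name: getattr(c.protocol, n),
            lambda d, v, n=f.name: d["protocol"].__setitem__(n, v))

    for drug in ANTICOAGULANTS:
        for attr in ("baseline_mean", "baseline_cv",
                     "sensitivity_mean", "sensitivity_cv"):
            add(f"population.{drug}.{attr}", float,
                lambda c, d=drug, a=attr: getattr(c.population.drugs[d], a),
                lambda dd, v, d=drug, a=attr: dd["drugs"][d].__setitem__(a, v))
        add(f"population.mix.{drug}", float,
            lambda c, d=drug: c.population.mix.get(d, 0.0),
            lambda dd, v, d=drug: dd["mix"].__setitem__(d, v))
    for name, typ in (
        ("weight_mean", float), ("weight_cv", float),
        ("elim_vmax_mean", float), ("elim_vmax_cv", float),
        ("elim_km", float), ("half_life", float),
        ("saturable", bool), ("assay_cv", float),
    ):
        add(f"population.{name}", typ,
            lambda c, n=name: getattr(c.population, n),
            lambda d, v, n=name: d["population"].__setitem__(n, v))

    for f in fields(ManualPolicy):
        add(f"manual.{f.name}", float,
            lambda c, n=f.name: getattr(c.manual, n),
            lambda d, v, n=f.name: d["manual"].__setitem__(n, v))

    add("trial.n_control", int, lambda c: c.n_control,
        lambda d, v: d["top"].__setitem__("n_control", v))
    add("trial.n_algo", int, lambda c: c.n_algo,
        lambda d, v: d["top"].__setitem__("n_algo", v))
    add("trial.duration", float, lambda c: c.duration,
        lambda d, v: d["top"].__setitem__("duration", v))
    add("trial.seed", int, lambda c: c.seed,
        lambda d, v: d["top"].__setitem__("seed", v))
    return schema


_SCHEMA = _schema()


def _bags(defaults: RunConfig) -> dict:
    """Mutable field bags prefilled from a default config."""
    return {
        "goal": {n: getattr(defaults.goal, n)
                 for n in ("low", "high", "center", "supra_threshold")},
        "bolus_rates": dict(defaults.protocol.bolus_rates),
        "infusion_rates": dict(defaults.protocol.infusion_rates),
        "protocol": {f.name: getattr(defaults.protocol, f.name)
                     for f in fields(ProtocolParams)
                     if f.name not in ("bolus_rates", "infusion_rates")},
        "drugs": {d: {a: getattr(defaults.population.drugs[d], a)
                      for a in ("baseline_mean", "baseline_cv",
                                "sensitivity_mean", "sensitivity_cv")}
                  for d in ANTICOAGULANTS},
        "mix": dict(defaults.population.mix),
        "population": {n: getattr(defaults.population, n)
                       for n in ("weight_mean", "weight_cv", "elim_vmax_mean",
                                 "elim_vmax_cv", "elim_km", "half_life",
                                 "saturable", "assay_cv")},
        "manual": {f.name: getattr(defaults.manual, f.name)
                   for f in fields(ManualPolicy)},
        "top": {"n_control": defaults.n_control, "n_algo": defaults.n_algo,
                "duration": defaults.duration, "seed": defaults.seed},
    }


def _build(bags: dict) -> RunConfig:
    try:
        goal = GoalRange(**bags["goal"])
        protocol = ProtocolParams(
            bolus_rates=bags["bolus_rates"],
            infusion_rates=bags["infusion_rates"],
            **bags["protocol"],
        )
        population = PopulationSpec(
            drugs={d: DrugPopulation(**a) for d, a in bags["drugs"].items()},
            mix=bags["mix"],
            **bags["population"],
        )
        manual = ManualPolicy(**bags["manual"])
        return RunConfig(goal=goal, protocol=protocol, population=population,
                         manual=manual, **bags["top"])
    except (ValidationError, ConfigError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def load_config(path) -> RunConfig:
    """Parse and validate a flat config file; unknown keys are an error."""
    bags = _bags(RunConfig())
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            if "=" not in stripped:
                raise ConfigError(
                    f"{path}:{lineno}: expected 'key = value', got {stripped!r}"
                )
            key, _, raw = stripped.partition("=")
            key = key.strip()
            if key not in _SCHEMA:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            typ, _get, put = _SCHEMA[key]
            try:
                value = _parse(raw, typ)
            except ValueError as exc:
                raise ConfigError(
                    f"{path}:{lineno}: bad value for {key}: {exc}"
                ) from exc
            put(bags, value)
    return _build(bags)


def dump_config(config: RunConfig, path) -> None:
    """Write every schema key so the file is a complete run description."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# actdose run configuration\n")
        for key, (typ, get, _put) in _SCHEMA.items():
            fh.write(f"{key} = {_fmt(get(config))}\n")


# ---------------------------------------------------------------------------
# Session logs
# ---------------------------------------------------------------------------

_SESSION_HEADER = "time_min\tevent_kind\tact_s\tbolus_units\tinfusion_units_per_h\tS\trationale"


def write_session(case: CaseRecord, path, profile=None,
                  annotations: Optional[dict] = None) -> None:
    """Write one case as a line-delimited session log.

    ``annotations`` may map an event's position in ``case.events`` to a
    ``(sensitivity, rationale)`` pair for the informational columns.
    ``profile`` (when given) adds the patient descriptors the dosing CLI
    needs to resume a session.
    """
    annotations = annotations or {}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# arm = {case.arm}\n")
        fh.write(f"# transseptal_time = {case.transseptal_time!r}\n")
        fh.write(f"# la_exit_time = {case.la_exit_time!r}\n")
        fh.write(f"# duration = {case.duration!r}\n")
        if profile is not None:
            fh.write(f"# anticoagulant = {profile.anticoagulant}\n")
            fh.write(f"# weight = {profile.weight!r}\n")
            fh.write(f"# baseline_act = {profile.baseline_act!r}\n")
        fh.write(_SESSION_HEADER + "\n")
        for i, ev in enumerate(case.events):
            s, rationale = annotations.get(i, ("", ""))
            s_txt = "" if s == "" else repr(s)
            if isinstance(ev, ActMeasurement):
                suspect = "act_suspect" if ev.flagged_suspect else rationale
                fh.write(
                    f"{ev.time!r}\tact\t{ev.value!r}\t\t\t{s_txt}\t{suspect}\n"
                )
            else:
                if ev.kind == "bolus":
                    fh.write(
                        f"{ev.time!r}\tbolus\t\t{ev.bolus_units!r}\t\t{s_txt}\t{rationale}\n"
                    )
                else:
                    fh.write(
                        f"{ev.time!r}\tinfusion_change\t\t\t"
                        f"{ev.new_infusion_rate!r}\t{s_txt}\t{rationale}\n"
                    )


def read_session(path):
    """Re-read a session log into ``(CaseRecord, metadata dict)``.

    Raises :class:`SessionFormatError` (with the offending line number)
    on malformed rows or out-of-order timestamps.
    """
    meta: dict = {}
    events: list = []
    header_seen = False
    last_time = None
    act_index = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            raw = line.rstrip("\n")
            if not raw.strip():
                continue
            if raw.startswith("#"):
                body = raw[1:].strip()
                if "=" in body:
                    k, _, v = body.partition("=")
                    meta[k.strip()] = v.strip()
                continue
            if not header_seen:
                if raw != _SESSION_HEADER:
                    raise SessionFormatError(
                        f"{path}:{lineno}: expected session header row"
                    )
                header_seen = True
                continue
            parts = raw.split("\t")
            if len(parts) != 7:
                raise SessionFormatError(
                    f"{path}:{lineno}: expected 7 tab-separated fields, "
                    f"got {len(parts)}"
                )
            t_raw, kind, act_s, bolus, inf, _s, _rat = parts
            try:
                t = float(t_raw)
            except ValueError:
                raise SessionFormatError(
                    f"{path}:{lineno}: bad time {t_raw!r}"
                ) from None
            if last_time is not None and t < last_time:
                raise SessionFormatError(
                    f"{path}:{lineno}: out-of-order timestamp {t!r}"
                )
            last_time = t
            try:
                if kind == "act":
                    ev = ActMeasurement(
                        time=t, value=float(act_s), index=act_index,
                        flagged_suspect=(_rat == "act_suspect"),
                    )
                    act_index += 1
                elif kind == "bolus":
                    ev = DoseEvent(t, "bolus", float(bolus))
                elif kind == "infusion_change":
                    ev = DoseEvent(t, "infusion_change", 0.0, float(inf))
                else:
                    raise SessionFormatError(
                        f"{path}:{lineno}: unknown event kind {kind!r}"
                    )
            except (ValueError, ValidationError) as exc:
                if isinstance(exc, SessionFormatError):
                    raise
                raise SessionFormatError(f"{path}:{lineno}: {exc}") from exc
            events.append(ev)

    if not header_seen:
        raise SessionFormatError(f"{path}: missing session header row")
    arm = meta.get("arm", "algorithm")
    duration = float(meta.get("duration", last_time or 0.0))
    transseptal = float(meta.get("transseptal_time", duration))
    la_exit = float(meta.get("la_exit_time", duration))
    case = CaseRecord(arm, events, transseptal, la_exit, duration)
    return case, meta
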