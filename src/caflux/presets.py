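"""Named generator presets for the experimental conditions.

Each preset populates a :class:`~caflux.config.GeneratorConfig` with the
summary kinetics reported for that condition (whole-cell event rate, peak
amplitude, FDHM, spatial spread, propagation velocity).  Where a condition's
report leaves a parameter unchanged from control, the baseline value is kept.

``baseline`` is the nerve-stimulation experiment: pre-EFS kinetics plus a
10 Hz, 5 s EFS train at t = 10 s with the per-site escape-latency model
(pooled latency 3.8 +/- 1.8 s clipped to [0.2, 9.9] s).
"""

from __future__ import annotations

from .config import EFSProtocol, GeneratorConfig


def _efs(onset: float = 10.0) -> EFSProtocol:
    return EFSProtocol(onset=onset)


def _baseline(**kw) -> GeneratorConfig:
    cfg = GeneratorConfig(efs=_efs())
    return cfg.replace(**kw) if kw else cfg


# Condition -> config factory.  Pharmacological presets model steady-state
# (no EFS) recordings unless noted.
_PRESETS = {
    # pre-EFS kinetics + EFS train with escape model
    "baseline": lambda: _baseline(),
    "baseline_efs": lambda: _baseline(),
    # NOS blockade: raised firing rate, slightly longer events, no EFS inhibition
    "lnna": lambda: GeneratorConfig(cell_rate=2.5, fdhm=250.0),
    # NO donor: strong suppression of rate and event size
    "deanonoate": lambda: GeneratorConfig(
        cell_rate=0.14, amp_mean=0.2, fdhm=66.0, spread=1.8, velocity=30.0
    ),
    # control arm of the NO-donor experiments
    "deanonoate_control": lambda: GeneratorConfig(cell_rate=0.9, amp_mean=0.7, fdhm=242.0, spread=8.9),
    # sGC inhibition: disinhibited basal firing
    "odq": lambda: GeneratorConfig(cell_rate=2.1),
    # sGC activator: suppression comparable to the NO donor
    "bay58": lambda: GeneratorConfig(
        cell_rate=0.2, amp_mean=0.1, fdhm=72.0, spread=2.7, velocity=30.0
    ),
    # VIP: near-complete suppression
    "vip": lambda: GeneratorConfig(cell_rate=0.08, amp_mean=0.2, fdhm=66.0, spread=5.0),
    # VIP receptor antagonist: disinhibited basal firing
    "vip6_28": lambda: GeneratorConfig(cell_rate=3.3),
}


def available_presets() -> list[str]:
    return sorted(_PRESETS)


def preset(name: str) -> GeneratorConfig:
    """Return a fully populated generator config for a named condition.

    Raises
    ------
    KeyError
        If ``name`` is unknown; the message lists the valid choices.
    """
    key = name.lower().replace("-", "_")
    try:
        factory = _PRESETS[key]
    except KeyError:
        raise KeyError(
            f"unknown preset {name!r}; choose one of: {', '.join(available_presets())}"
        ) from None
    cfg = factory()
    cfg.validate()
    return cfg
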