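"""Connection building: deterministic rules plus value/array/distribution parameters.

Five wiring rules are supported: ``one_to_one``, ``all_to_all``,
``fixed_indegree``, ``fixed_outdegree`` and ``fixed_total_number``.  Weights
and delays may be given as scalars, as per-connection arrays, or as
distribution specifications (currently the clipped normal, which is what the
benchmark networks use for their delay spread).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

__all__ = ["ConnSpec", "SynSpec", "connect", "draw_delay", "ConnectionList"]

RULES = ("one_to_one", "all_to_all", "fixed_indegree", "fixed_outdegree",
         "fixed_total_number")


@dataclass
class ConnSpec:
    """How two node groups are wired together."""

    rule: str = "all_to_all"
    indegree: Optional[int] = None
    outdegree: Optional[int] = None
    total_number: Optional[int] = None
    allow_autapses: bool = True
    allow_multapses: bool = True

    def __post_init__(self):
        if self.rule not in RULES:
            raise ValueError(f"unknown connection rule {self.rule!r}")
        for name in ("indegree", "outdegree", "total_number"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SynSpec:
    """Synaptic parameters attached to every connection a rule creates.

    ``weight`` is in pA for current-based targets and nS (peak conductance)
    for conductance-based targets.  ``delay`` is in ms and is quantized to
    simulation steps later, during network calibration.
    """

    weight: Union[float, np.ndarray, dict] = 1.0
    delay: Union[float, np.ndarray, dict] = 1.0
    receptor: int = 0
    synapse: str = "static"          # "static" | "stdp"
    stdp_params: Optional[object] = None
    dendritic_delay: float = 0.0     # ms; uniform over this specification

    def __post_init__(self):
        if self.synapse not in ("static", "stdp"):
            raise ValueError(f"unknown synapse kind {self.synapse!r}")
        if self.synapse == "stdp" and self.stdp_params is None:
            raise ValueError("stdp synapse requires stdp_params")


def _resolve(value, size, rng, clip_min=None, clip_max=None):
    """Expand a scalar/array/distribution parameter to a length-``size`` array."""
    if isinstance(value, dict):
        dist = value.get("distribution", "normal")
        if dist != "normal":
            raise ValueError(f"unsupported distribution {dist!r}")
        out = rng.normal(value["mean"], value.get("std", 0.0), size=size)
        lo = value.get("min", clip_min)
        hi = value.get("max", clip_max)
    else:
        out = np.broadcast_to(np.asarray(value, dtype=float), (size,)).copy()
        lo, hi = clip_min, clip_max
    if lo is not None:
        np.maximum(out, lo, out=out)
    if hi is not None:
        np.minimum(out, hi, out=out)
    return out


def draw_delay(dist, rng, dt, size=1):
    """Draw connection delays (ms), clipping any value below one step to ``dt``.

    Clipping rather than resampling introduces a negligible bias at the
    benchmark operating point (mean delay of five steps).
    """
    out = _resolve(dist, size, rng, clip_min=dt)
    return out


def _draw_no_autapse(rng, n_source, targets, size_per_target, sources_eq_targets):
    """fixed-indegree draws with replacement, resampling self-connections."""
    draws = rng.integers(0, n_source, size=(len(targets), size_per_target))
    if sources_eq_targets:
        bad = draws == targets[:, None]
        while bad.any():
            draws[bad] = rng.integers(0, n_source, size=int(bad.sum()))
            bad = draws == targets[:, None]
    return draws


def connect(sources, targets, conn: ConnSpec, syn: SynSpec, rng, dt=0.1):
    """Realize a connection rule between two id arrays.

    Returns ``(src, tgt, weight, delay)`` integer/float arrays, one entry per
    connection.  Connectivity is a pure function of the generator state, so a
    fixed seed and build order give a reproducible network.
    """
    sources = np.asarray(sources, dtype=np.int64)
    targets = np.asarray(targets, dtype=np.int64)
    if sources.size == 0 or targets.size == 0:
        raise ValueError("source and target groups must be non-empty")
    ns, nt = sources.size, targets.size
    same_group = ns == nt and np.array_equal(sources, targets)

    if conn.rule == "one_to_one":
        if ns != nt:
            raise ValueError("one_to_one requires equally sized groups")
        src, tgt = sources.copy(), targets.copy()
    elif conn.rule == "all_to_all":
        src = np.repeat(sources, nt)
        tgt = np.tile(targets, ns)
        if not conn.allow_autapses:
            keep = src != tgt
            src, tgt = src[keep], tgt[keep]
    elif conn.rule == "fixed_indegree":
        k = conn.indegree
        if k is None:
            raise ValueError("fixed_indegree requires indegree")
        if conn.allow_multapses:
            if conn.allow_autapses:
                picks = rng.integers(0, ns, size=(nt, k))
            else:
                picks = _draw_no_autapse(rng, ns, targets, k, same_group)
            src = sources[picks.ravel()]
            tgt = np.repeat(targets, k)
        else:
            avail = ns - (1 if (same_group and not conn.allow_autapses) else 0)
            if k > avail:
                raise ValueError("indegree exceeds available sources "
                                 "with multapses disallowed")
            cols = []
            for t in targets:
                pool = sources
                if same_group and not conn.allow_autapses:
                    pool = sources[sources != t]
                cols.append(rng.choice(pool, size=k, replace=False))
            src = np.concatenate(cols)
            tgt = np.repeat(targets, k)
    elif conn.rule == "fixed_outdegree":
        k = conn.outdegree
        if k is None:
            raise ValueError("fixed_outdegree requires outdegree")
        if conn.allow_multapses:
            if conn.allow_autapses:
                picks = rng.integers(0, nt, size=(ns, k))
            else:
                picks = _draw_no_autapse(rng, nt, sources, k, same_group)
            tgt = targets[picks.ravel()]
            src = np.repeat(sources, k)
        else:
            avail = nt - (1 if (same_group and not conn.allow_autapses) else 0)
            if k > avail:
                raise ValueError("outdegree exceeds available targets "
                                 "with multapses disallowed")
            cols = []
            for s in sources:
                pool = targets
                if same_group and not conn.allow_autapses:
                    pool = targets[targets != s]
                cols.append(rng.choice(pool, size=k, replace=False))
            tgt = np.concatenate(cols)
            src = np.repeat(sources, k)
    elif conn.rule == "fixed_total_number":
        n = conn.total_number
        if n is None:
            raise ValueError("fixed_total_number requires total_number")
        si = rng.integers(0, ns, size=n)
        ti = rng.integers(0, nt, size=n)
        src, tgt = sources[si], targets[ti]
        if not conn.allow_autapses:
            bad = src == tgt
            while bad.any():
                m = int(bad.sum())
                src[bad] = sources[rng.integers(0, ns, size=m)]
                tgt[bad] = targets[rng.integers(0, nt, size=m)]
                bad = src == tgt
    else:  # pragma: no cover - guarded by ConnSpec
        raise ValueError(conn.rule)

    m = src.size
    weight = _resolve(syn.weight, m, rng)
    delay = draw_delay(syn.delay, rng, dt, size=m)
    return src, tgt, weight, delay


@dataclass
class ConnectionList:
    """Growable builder holding every connection before calibration."""

    src: list = field(default_factory=list)
    tgt: list = field(default_factory=list)
    weight: list = field(default_factory=list)
    delay: list = field(default_factory=list)
    port: list = field(default_factory=list)
    kind: list = field(default_factory=list)          # 0 static, 1 stdp
    param_set: list = field(default_factory=list)     # stdp parameter-set id
    stdp_param_sets: list = field(default_factory=list)
    dendritic_delay: list = field(default_factory=list)

    def extend(self, src, tgt, weight, delay, syn: SynSpec):
        m = len(src)
        self.src.append(np.asarray(src, dtype=np.int64))
        self.tgt.append(np.asarray(tgt, dtype=np.int64))
        self.weight.append(np.asarray(weight, dtype=float))
        self.delay.append(np.asarray(delay, dtype=float))
        self.port.append(np.full(m, syn.receptor, dtype=np.int8))
        if syn.synapse == "stdp":
            pid = len(self.stdp_param_sets)
            self.stdp_param_sets.append(syn.stdp_params)
            self.kind.append(np.ones(m, dtype=np.int8))
            self.param_set.append(np.full(m, pid, dtype=np.int16))
            self.dendritic_delay.append(np.full(m, syn.dendritic_delay))
        else:
            self.kind.append(np.zeros(m, dtype=np.int8))
            self.param_set.append(np.full(m, -1, dtype=np.int16))
            self.dendritic_delay.append(np.zeros(m))

    @property
    def n_connections(self):
        return int(sum(a.size for a in self.src))

    def concatenated(self):
        if not self.src:
            z = np.zeros(0)
            return (z.astype(np.int64), z.astype(np.int64), z, z,
                    z.astype(np.int8), z.astype(np.int8),
                    z.astype(np.int16), z)
        return (np.concatenate(self.src), np.concatenate(self.tgt),
                np.concatenate(self.weight), np.concatenate(self.delay),
                np.concatenate(self.port), np.concatenate(self.kind),
                np.concatenate(self.param_set),
                np.concatenate(self.dendritic_delay))
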