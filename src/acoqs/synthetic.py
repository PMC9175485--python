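"""Synthetic FASTQ generator with the statistical structure the codec exploits.

Real short-read quality data show four regularities the compound context
model targets, and the generator realizes each one through an independent
switch so ablation experiments are possible:

* per-cycle drift: the mean quality decreases along the read while the
  noise level grows (``mean_slope``, ``noise_sd_slope``);
* within-read correlation: AR(1) noise along the cycle axis (``ar1_rho``);
* cross-read correlation: reads adjacent in the file come from neighbouring
  clusters on the flowcell, whose readouts bleed into each other, so both
  the per-read level and the cycle noise are AR-correlated across
  consecutive reads (``cross_read_rho``);
* per-read level variation: a slowly varying read-level offset
  (``read_level_sd``) -- the structure the row-mean context captures;
* base-change dips: residual signal from the previous incorporation can
  depress the quality where the base differs from its predecessor
  (``base_change_dip``, ``dip_prob``) -- the structure the second-order
  base context captures.

The model is a test instrument emulating these observables, not a claim
about sequencer physics.  Output is deterministic given the config and
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Tuple, Union

import numpy as np

from .fastq_io import FastqRecord

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SyntheticConfig:
    """Generator parameters (all quality units are Phred scores)."""

    n_reads: int = 10_000
    #: fixed length, or an inclusive (min, max) range for ragged output
    read_len: Union[int, Tuple[int, int]] = 100
    seed: int = 0
    mean_start: float = 38.0
    mean_slope: float = -0.05
    noise_sd_start: float = 2.0
    noise_sd_slope: float = 0.02
    ar1_rho: float = 0.8
    cross_read_rho: float = 0.95
    read_level_sd: float = 2.5
    base_change_dip: float = 4.0
    dip_prob: float = 0.1
    qmax: int = 41

    def validate(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be non-negative")
        if isinstance(self.read_len, tuple):
            lo, hi = self.read_len
            if not 0 <= lo <= hi:
                raise ValueError("invalid read_len range")
        elif self.read_len < 0:
            raise ValueError("read_len must be non-negative")
        for name in ("ar1_rho", "cross_read_rho"):
            v = getattr(self, name)
            if not 0.0 <= v < 1.0:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name in ("mean_start", "mean_slope", "noise_sd_start",
                     "noise_sd_slope", "read_level_sd", "base_change_dip",
                     "dip_prob"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.dip_prob <= 1.0:
            raise ValueError("dip_prob must lie in [0, 1]")
        if self.qmax < 0:
            raise ValueError("qmax must be non-negative")


def generate(config: SyntheticConfig) -> List[FastqRecord]:
    """Draw a synthetic FASTQ file as a list of records.

    Quality of read r at cycle c is
    ``clip(round(mean_start + mean_slope*c + u_r + e_{r,c} - dip_{r,c}), 0, qmax)``
    where ``u`` is an AR(1)-across-reads level offset, ``e`` a separable 2-D
    AR field (AR(1) along cycles, innovations AR(1) across reads, marginal
    sd growing with the cycle), and ``dip`` subtracts ``base_change_dip``
    where the base differs from its predecessor and a Bernoulli draw fires.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    if isinstance(config.read_len, tuple):
        lo, hi = config.read_len
        lengths = rng.integers(lo, hi + 1, size=n)
    else:
        lengths = np.full(n, int(config.read_len), dtype=np.int64)
    lmax = int(lengths.max()) if n else 0
    if n == 0 or lmax == 0:
        return [FastqRecord(f"sim_{i}", "", np.empty(0, dtype=np.uint8))
                for i in range(n)]

    base_idx = rng.integers(0, 4, size=(n, lmax))

    # read-level offset, AR(1) across consecutive reads
    rho_u = config.cross_read_rho
    zu = rng.standard_normal(n)
    u = np.empty(n)
    u[0] = zu[0]
    scale = np.sqrt(1.0 - rho_u * rho_u)
    for r in range(1, n):
        u[r] = rho_u * u[r - 1] + scale * zu[r]
    u *= config.read_level_sd

    # separable AR noise: innovations AR(1) across reads, then AR(1) along cycles
    z = rng.standard_normal((n, lmax))
    w = np.empty_like(z)
    w[0] = z[0]
    for r in range(1, n):
        w[r] = rho_u * w[r - 1] + scale * z[r]
    sd_c = config.noise_sd_start + config.noise_sd_slope * np.arange(lmax)
    sd_c = np.maximum(sd_c, 0.0)
    rho_c = config.ar1_rho
    hscale = np.sqrt(1.0 - rho_c * rho_c)
    e = np.empty_like(w)
    e[:, 0] = sd_c[0] * w[:, 0]
    for c in range(1, lmax):
        e[:, c] = rho_c * e[:, c - 1] + hscale * sd_c[c] * w[:, c]

    dip = np.zeros((n, lmax))
    if config.base_change_dip != 0.0 and config.dip_prob > 0.0:
        change = np.zeros((n, lmax), dtype=bool)
        change[:, 1:] = base_idx[:, 1:] != base_idx[:, :-1]
        fires = rng.random((n, lmax)) < config.dip_prob
        dip = np.where(change & fires, config.base_change_dip, 0.0)

    mu = config.mean_start + config.mean_slope * np.arange(lmax)
    q = mu[None, :] + u[:, None] + e - dip
    qi = np.clip(np.rint(q), 0, config.qmax).astype(np.uint8)

    base_chars = _BASES[base_idx]
    records = []
    for i in range(n):
        ln = int(lengths[i])
        records.append(FastqRecord(
            f"sim_{i}",
            base_chars[i, :ln].tobytes().decode("ascii"),
            qi[i, :ln].copy()))
    return records


#: Named parameter sets for the structures the contexts target.
_PRESETS = {
    # the full regime: drift, AR noise, cross-read correlation, level
    # spread, and base-change dips all on
    "paper-like": {},
    # memoryless control: every structural switch off
    "iid": dict(mean_slope=0.0, noise_sd_start=1.5, noise_sd_slope=0.0,
                ar1_rho=0.0, cross_read_rho=0.0, read_level_sd=0.0,
                base_change_dip=0.0, dip_prob=0.0, mean_start=35.0),
    # only the base-change mechanism, to isolate the base-context benefit
    "dips-only": dict(mean_slope=0.0, noise_sd_start=1.0, noise_sd_slope=0.0,
                      ar1_rho=0.0, cross_read_rho=0.0, read_level_sd=0.0,
                      base_change_dip=5.0, dip_prob=0.4, mean_start=38.0),
    # only per-read level variation (spread >= 4 Phred), to isolate the
    # row-mean benefit from drift, AR noise and cross-read correlation
    "row-spread": dict(mean_slope=0.0, noise_sd_start=1.5, noise_sd_slope=0.0,
                       ar1_rho=0.0, cross_read_rho=0.0, read_level_sd=4.0,
                       base_change_dip=0.0, dip_prob=0.0, mean_start=36.0),
}


def preset(name: str, n_reads: int = 10_000, read_len: int = 100,
           seed: int = 0) -> SyntheticConfig:
    """A named :class:`SyntheticConfig` (see module docstring for the menu)."""
    try:
        overrides = _PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; choose from {sorted(_PRESETS)}") from None
    return replace(SyntheticConfig(n_reads=n_reads, read_len=read_len, seed=seed),
                   **overrides)
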