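"""Unit conventions shared by every module.

The engine works in reduced units: energies in kcal/mol, lengths in Å,
temperatures in kcal/(mol·kB).  Two fixed constants tie these to laboratory
units:

* ``KB`` = 0.002 kcal/mol/K converts reduced temperature to Kelvin, so a
  reduced temperature of 0.6 corresponds to 300 K.
* one reduced time unit (t.u.) corresponds to 50 fs, so 2×10⁴ steps ≈ 1 ns.

A convenient consequence of choosing (kcal/mol, Å, 50 fs) as base units is
that the derived mass unit is ≈1.05 g/mol, so bead masses can be quoted in
Daltons to good accuracy.
"""

from __future__ import annotations

KB: float = 0.002
"""Boltzmann constant, kcal/mol/K, fixing the reduced-temperature scale."""

TIME_UNIT_FS: float = 50.0
"""Physical duration of one reduced time unit, femtoseconds."""

_NS_PER_STEP = TIME_UNIT_FS * 1e-6


def reduced_to_kelvin(t_reduced: float) -> float:
    """Convert a reduced temperature (kcal/(mol·kB)) to Kelvin."""
    if t_reduced <= 0:
        raise ValueError(f"temperature must be positive, got {t_reduced}")
    return t_reduced / KB


def kelvin_to_reduced(t_kelvin: float) -> float:
    """Convert Kelvin to reduced temperature units."""
    if t_kelvin <= 0:
        raise ValueError(f"temperature must be positive, got {t_kelvin}")
    return t_kelvin * KB


def steps_to_ns(steps: float) -> float:
    """Convert a number of time units to nanoseconds (2e4 steps -> 1 ns)."""
    if steps < 0:
        raise ValueError(f"step count must be non-negative, got {steps}")
    return steps * _NS_PER_STEP


def ns_to_steps(ns: float) -> float:
    """Inverse of :func:`steps_to_ns`."""
    if ns < 0:
        raise ValueError(f"duration must be non-negative, got {ns}")
    return ns / _NS_PER_STEP
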