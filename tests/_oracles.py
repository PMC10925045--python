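"""Independent direct-evaluation oracles, coded separately from the package.

These deliberately use plain ``math`` with explicit accumulation loops so
they share no code path with the vectorised implementation they check.
"""

import math


def vertical_term_oracle(h: float, delta_z: float, l: float, n_reflections: int) -> float:
    dz2 = 2.0 * delta_z * delta_z
    total = 2.0 * math.exp(-(h * h) / dz2)
    for n in range(1, n_reflections + 1):
        total += math.exp(-((n * l - h) ** 2) / dz2)
        total += math.exp(-((n * l + h) ** 2) / dz2)
    return total


def concentration_oracle(
    E: float,
    y: float,
    mu: float,
    delta_y: float,
    delta_z: float,
    h: float,
    l: float,
    n_reflections: int,
    unit_scale: float = 1.0,
) -> float:
    p = vertical_term_oracle(h, delta_z, l, n_reflections)
    prefactor = E / (2.0 * math.pi * mu * delta_y * delta_z)
    lateral = math.exp(-(y * y) / (2.0 * delta_y * delta_y))
    return unit_scale * prefactor * lateral * p


def mean_concentration_oracle(
    E: float,
    offsets,
    mu: float,
    delta_y: float,
    delta_z: float,
    h: float,
    l: float,
    n_reflections: int,
    unit_scale: float = 1.0,
) -> float:
    acc = 0.0
    for y in offsets:
        acc += concentration_oracle(E, y, mu, delta_y, delta_z, h, l, n_reflections, unit_scale)
    return acc / len(offsets)
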