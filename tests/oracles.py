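"""Independently coded scalar duplicates of every closed-form operation.

These are deliberately written from the formulas with plain ``math`` calls
and no shared code with the package, so that agreement with the vectorized
implementations is a genuine double-entry check.
"""

import math

P0 = 101325.0
R = 8.3145
TREF = 298.15


def pressure(z):
    return P0 * (1.0 - 0.0065 * z / 288.15) ** (9.80665 * 0.028963 / (R * 0.0065))


def gammastar(t, z, g25=4.332, dha=37830.0):
    return g25 * pressure(z) / P0 * math.exp((dha / R) * (1 / TREF - 1 / (t + 273.15)))


def kmm(t, z, kc25=39.97, dkc=79430.0, ko25=27480.0, dko=36380.0, fo2=0.20946):
    kc = kc25 * math.exp((dkc / R) * (1 / TREF - 1 / (t + 273.15)))
    ko = ko25 * math.exp((dko / R) * (1 / TREF - 1 / (t + 273.15)))
    return kc * (1.0 + fo2 * pressure(z) / ko)


def eta_star(t):
    return math.exp(507.88 / (t + 273.15 - 149.3)) / math.exp(507.88 / (TREF - 149.3))


def chi_c3(t, vpd, ca, z, beta=146.0):
    gs = gammastar(t, z)
    xi = math.sqrt(beta * (kmm(t, z) + gs) / (1.6 * eta_star(t)))
    return gs / ca + (1 - gs / ca) * xi / (xi + math.sqrt(vpd))


def mj(chi, ca, gs):
    ci = chi * ca
    return (ci - gs) / (ci + 2 * gs)


def delta3(chi, gs_over_ca, a=4.4, b=28.0, f=12.0):
    return a + (b - a) * chi - f * gs_over_ca


def delta4(chi4, a=4.4, b4=-7.9, phi=0.21, b=30.0):
    return a + (b4 + phi * b - a) * chi4


def f4_pot(share):
    return min(max(share / 1.13, 0.0), 1.0)


def f4_nat(f4p, f3c, f4c, urb):
    return max(f4p - (f3c + f4c) - urb, 0.0)


def totals(f4n, f4c):
    f4 = min(f4n + f4c, 1.0)
    return f4, 1.0 - f4


def partition(g3p, g4p, f3, f4):
    return g3p * f3, g4p * f4, g3p * f3 + g4p * f4


def weighted_delta(deltas, gpps):
    return sum(d * g for d, g in zip(deltas, gpps)) / sum(gpps)


def cue_fraction(f_t0, f_t, cue):
    return f_t0 - (f_t0 - f_t) * cue


def land_delta(f4, f3h, f3w, d3, d4, t4=2.4, t3h=24.4, t3w=299.4):
    return (f4 * d4 * t4 + f3h * d3 * t3h + f3w * d3 * t3w) / (t4 + t3h + t3w)


def to_small_delta(Delta, d_atm):
    return (d_atm - Delta) / (1 + Delta / 1000.0)


def to_Delta(d_plant, d_atm):
    return (d_atm - d_plant) / (1 + d_plant / 1000.0)


def soil_d13c(f3s, f4s, d3s, d4s):
    vals = [f3 * d3 + f4 * d4 for f3, f4, d3, d4 in zip(f3s, f4s, d3s, d4s)]
    return sum(vals) / len(vals)
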