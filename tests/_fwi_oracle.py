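"""Independent scalar transcription of the standard FWI System updates.

Written directly from the published closed-form daily equations as plain
branching scalar code, kept deliberately separate from the package's
vectorised engine so the two can be compared as independent routes.
"""

import math

DMC_DAY_LENGTH = [6.5, 7.5, 9.0, 12.8, 13.9, 13.9, 12.4, 10.9, 9.4, 8.0, 7.0, 6.0]
DC_DAY_LENGTH = [-1.6, -1.6, -1.6, 0.9, 3.8, 5.8, 6.4, 5.0, 2.4, 0.4, -1.6, -1.6]


def ffmc_next(f0, t, h, w, p):
    m = 147.2 * (101.0 - f0) / (59.5 + f0)
    if p > 0.5:
        rf = p - 0.5
        if m > 150.0:
            m = (
                m
                + 42.5 * rf * math.exp(-100.0 / (251.0 - m)) * (1.0 - math.exp(-6.93 / rf))
                + 0.0015 * (m - 150.0) ** 2 * math.sqrt(rf)
            )
        else:
            m = m + 42.5 * rf * math.exp(-100.0 / (251.0 - m)) * (1.0 - math.exp(-6.93 / rf))
        if m > 250.0:
            m = 250.0
    ed = (
        0.942 * h**0.679
        + 11.0 * math.exp((h - 100.0) / 10.0)
        + 0.18 * (21.1 - t) * (1.0 - math.exp(-0.115 * h))
    )
    if m > ed:
        ko = 0.424 * (1.0 - (h / 100.0) ** 1.7) + 0.0694 * math.sqrt(w) * (
            1.0 - (h / 100.0) ** 8
        )
        kd = ko * 0.581 * math.exp(0.0365 * t)
        m = ed + (m - ed) * 10.0**-kd
    else:
        ew = (
            0.618 * h**0.753
            + 10.0 * math.exp((h - 100.0) / 10.0)
            + 0.18 * (21.1 - t) * (1.0 - math.exp(-0.115 * h))
        )
        if m < ew:
            k1 = 0.424 * (1.0 - ((100.0 - h) / 100.0) ** 1.7) + 0.0694 * math.sqrt(w) * (
                1.0 - ((100.0 - h) / 100.0) ** 8
            )
            kw = k1 * 0.581 * math.exp(0.0365 * t)
            m = ew - (ew - m) * 10.0**-kw
    f = 59.5 * (250.0 - m) / (147.2 + m)
    return min(max(f, 0.0), 101.0)


def dmc_next(p0, t, h, p, month):
    if p > 1.5:
        re = 0.92 * p - 1.27
        mo = 20.0 + 280.0 / math.exp(0.023 * p0)
        if p0 <= 33.0:
            b = 100.0 / (0.5 + 0.3 * p0)
        elif p0 <= 65.0:
            b = 14.0 - 1.3 * math.log(p0)
        else:
            b = 6.2 * math.log(p0) - 17.2
        mr = mo + 1000.0 * re / (48.77 + b * re)
        pr = 43.43 * (5.6348 - math.log(mr - 20.0))
        if pr < 0.0:
            pr = 0.0
    else:
        pr = p0
    if t > -1.1:
        k = 1.894 * (t + 1.1) * (100.0 - h) * DMC_DAY_LENGTH[month - 1] * 1e-6
    else:
        k = 0.0
    return max(pr + 100.0 * k, 0.0)


def dc_next(d0, t, p, month):
    if p > 2.8:
        rd = 0.83 * p - 1.27
        qo = 800.0 * math.exp(-d0 / 400.0)
        qr = qo + 3.937 * rd
        dr = 400.0 * math.log(800.0 / qr)
        if dr < 0.0:
            dr = 0.0
    else:
        dr = d0
    if t < -2.8:
        t = -2.8
    v = 0.36 * (t + 2.8) + DC_DAY_LENGTH[month - 1]
    if v < 0.0:
        v = 0.0
    return max(dr + 0.5 * v, 0.0)


def isi_value(ffmc, w):
    m = 147.2 * (101.0 - ffmc) / (59.5 + ffmc)
    fw = math.exp(0.05039 * w)
    ff = 91.9 * math.exp(-0.1386 * m) * (1.0 + m**5.31 / 4.93e7)
    return 0.208 * fw * ff


def bui_value(dmc, dc):
    if dmc + 0.4 * dc == 0.0:
        return 0.0
    if dmc <= 0.4 * dc:
        u = 0.8 * dmc * dc / (dmc + 0.4 * dc)
    else:
        u = dmc - (1.0 - 0.8 * dc / (dmc + 0.4 * dc)) * (0.92 + (0.0114 * dmc) ** 1.7)
    return max(u, 0.0)


def fwi_value(isi, bui):
    if bui <= 80.0:
        fd = 0.626 * bui**0.809 + 2.0
    else:
        fd = 1000.0 / (25.0 + 108.64 * math.exp(-0.023 * bui))
    b = 0.1 * isi * fd
    if b > 1.0:
        s = math.exp(2.72 * (0.434 * math.log(b)) ** 0.647)
    else:
        s = b
    return max(s, 0.0)


def run_sequence(ffmc, dmc, dc, weather):
    """Run a daily sequence; ``weather`` yields (t, h, w, p, month).

    Returns a list of (ffmc, dmc, dc, isi, bui, fwi) per day.
    """
    out = []
    for (t, h, w, p, month) in weather:
        ffmc = ffmc_next(ffmc, t, h, w, p)
        dmc = dmc_next(dmc, t, h, p, month)
        dc = dc_next(dc, t, p, month)
        isi = isi_value(ffmc, w)
        bui = bui_value(dmc, dc)
        out.append((ffmc, dmc, dc, isi, bui, fwi_value(isi, bui)))
    return out


def overwinter_oracle(fall_dc, rw, a, b):
    q_fall = 800.0 * math.exp(-fall_dc / 400.0)
    q_spring = a * q_fall + b * 3.94 * rw
    return max(400.0 * math.log(800.0 / q_spring), 0.0)
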