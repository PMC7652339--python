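"""Independent, literal re-codings of the six kinetic readout formulas.

Deliberately naive plain-Python loops, kept free of any package internals so
they can serve as an oracle for the vectorised implementations.
"""


def fold_proliferation(e_live):
    return [e_live[i] / e_live[0] for i in range(len(e_live))]


def death_fraction(red_px, phase_px):
    return [red_px[i] / phase_px[i] * 100.0 for i in range(len(red_px))]


def specific_killing(td_c, td_0):
    return [td_c[i] / td_0[i] for i in range(len(td_c))]


def killing_per_tcell(td_c, e_c, td_0, e_0):
    out = [None]
    for i in range(1, len(td_c)):
        out.append((td_c[i] / e_c[i - 1]) / (td_0[i] / e_0[i - 1]))
    return out


def proliferation_rate(e_live):
    out = [None]
    for i in range(1, len(e_live)):
        out.append((e_live[i] - e_live[i - 1]) / e_live[i - 1] * 4.0)
    return out


def kill_rate(k, e_live):
    out = [None]
    for i in range(1, len(k)):
        out.append((k[i] - k[i - 1]) / e_live[i - 1] / 6.0)
    return out
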