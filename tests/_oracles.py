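"""Independent brute-force oracles used to cross-check the root finders.

These deliberately share no code with the package implementation: plain
bisection on the raw implicit equations, run far past the accuracy of the
production solvers.
"""


def bisect_loewe(model, conc_map, iters=200):
    """Bisection root of the dose-substitution equation."""
    active = [d for d in model.drugs if conc_map[d.drug_id] > 0]
    emax_min = min(d.emax for d in active)

    def gsum(e):
        total = -1.0
        for d in active:
            total += conc_map[d.drug_id] / (
                d.ec50 * (e / (d.emax - e)) ** (1.0 / d.hill)
            )
        return total

    lo, hi = emax_min * 1e-15, emax_min * (1 - 1e-15)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if gsum(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def bisect_greco(pd_a, pd_b, alpha, c_a, c_b, iters=200):
    """Bisection root of the Greco implicit equation."""
    emax_min = min(pd_a.emax, pd_b.emax)
    expo = 0.5 / pd_a.hill + 0.5 / pd_b.hill

    def gsum(e):
        return (
            c_a / (pd_a.ec50 * (e / (pd_a.emax - e)) ** (1 / pd_a.hill))
            + c_b / (pd_b.ec50 * (e / (pd_b.emax - e)) ** (1 / pd_b.hill))
            + alpha * c_a * c_b / (pd_a.ec50 * pd_b.ec50 * (e / (emax_min - e)) ** expo)
            - 1.0
        )

    lo, hi = emax_min * 1e-15, emax_min * (1 - 1e-15)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        if gsum(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
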