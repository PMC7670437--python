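"""Deliberately naive, straight-line reimplementations used as oracles.

Everything here is written directly from the governing equations with plain
Python loops and no shared code with the package internals, so that
agreement between the two routes is meaningful.
"""

import math

import numpy as np

GRID = [round(-0.025 + 0.001 * k, 6) for k in range(51)]


def naive_staverman_guggenheim(x, r, q, z=10.0):
    """Combinatorial ln gamma, literal phi/theta/l evaluation (x_i > 0)."""
    n = len(x)
    sx_r = sum(x[j] * r[j] for j in range(n))
    sx_q = sum(x[j] * q[j] for j in range(n))
    l = [z / 2.0 * (r[j] - q[j]) - (r[j] - 1.0) for j in range(n)]
    out = []
    for i in range(n):
        phi = x[i] * r[i] / sx_r
        theta = x[i] * q[i] / sx_q
        out.append(
            math.log(phi / x[i])
            + z / 2.0 * q[i] * math.log(theta / phi)
            + l[i]
            - phi / x[i] * sum(x[j] * l[j] for j in range(n))
        )
    return out


def naive_dw_2002(sm, sn, alpha_prime=16466.72, c_hb=85580.0, sigma_hb=0.0084):
    acc, don = max(sm, sn), min(sm, sn)
    return (alpha_prime / 2.0) * (sm + sn) ** 2 + c_hb * max(
        0.0, acc - sigma_hb
    ) * min(0.0, don + sigma_hb)


def naive_segment_fixed_point(p, dw, T, R=0.001987, iters=100_000):
    """Successive substitution with plain midpoint averaging.

    The raw map Gamma -> 1/sum(p Gamma K) two-cycles, so each step moves to
    the midpoint of the current iterate and the mapped one; run to machine
    precision.  Shares no code with the package's solver.
    """
    n = len(p)
    boltz = np.array(
        [[math.exp(-dw[m][k] / (R * T)) for k in range(n)] for m in range(n)]
    )
    p_arr = np.asarray(p, dtype=float)
    gamma = np.ones(n)
    for _ in range(iters):
        mapped = 1.0 / (boltz @ (p_arr * gamma))
        if np.max(np.abs(mapped - gamma)) < 1e-14:
            gamma = mapped
            break
        gamma = 0.5 * (mapped + gamma)
    return gamma.tolist()


def naive_cosmosac2002(
    profiles,
    areas,
    volumes,
    x,
    T,
    a_eff=7.50,
    alpha_prime=16466.72,
    c_hb=85580.0,
    sigma_hb=0.0084,
    q0=79.53,
    r0=66.69,
    z=10.0,
    R=0.001987,
):
    """ln gamma for every component; profiles are 51-value p_i lists."""
    nc = len(x)
    r = [volumes[i] / r0 for i in range(nc)]
    q = [areas[i] / q0 for i in range(nc)]
    comb = naive_staverman_guggenheim(x, r, q, z)

    dw = [[naive_dw_2002(GRID[m], GRID[k], alpha_prime, c_hb, sigma_hb)
           for k in range(51)] for m in range(51)]
    total_w = sum(x[i] * areas[i] for i in range(nc))
    p_mix = [
        sum(x[i] * areas[i] * profiles[i][m] for i in range(nc)) / total_w
        for m in range(51)
    ]
    ln_gs = [math.log(g) for g in naive_segment_fixed_point(p_mix, dw, T, R)]
    out = []
    for i in range(nc):
        ln_gi = [math.log(g) for g in naive_segment_fixed_point(profiles[i], dw, T, R)]
        n_i = areas[i] / a_eff
        resid = n_i * sum(
            profiles[i][m] * (ln_gs[m] - ln_gi[m]) for m in range(51)
        )
        out.append(comb[i] + resid)
    return out


def naive_dw_2010(sm, tm, sn, tn, T, a_es=6525.69, b_es=1.4859e8,
                  c_oh_oh=4013.78, c_ot_ot=932.31, c_oh_ot=3016.43,
                  hb_sign=-1.0):
    es = (a_es + b_es / T**2) * (sm + sn) ** 2
    pair = {tm, tn}
    if pair == {"OH"}:
        c = c_oh_oh
    elif pair == {"OT"}:
        c = c_ot_ot
    elif pair == {"OH", "OT"}:
        c = c_oh_ot
    else:
        c = 0.0
    hb = hb_sign * c * (sm - sn) ** 2 if sm * sn < 0 else 0.0
    return es + hb


def naive_cosmosac2010(
    split_profiles,
    areas,
    volumes,
    x,
    T,
    a_eff=7.50,
    q0=79.53,
    r0=66.69,
    z=10.0,
    R=0.001987,
    **dw_kw,
):
    """split_profiles: per component, dict {'NHB': 51 vals, 'OH': .., 'OT': ..}."""
    classes = ["NHB", "OH", "OT"]
    nc = len(x)
    r = [volumes[i] / r0 for i in range(nc)]
    q = [areas[i] / q0 for i in range(nc)]
    comb = naive_staverman_guggenheim(x, r, q, z)

    # stacked 153-segment system: (class, sigma) pairs
    labels = [(c, GRID[m]) for c in classes for m in range(51)]
    dw = [
        [naive_dw_2010(sm, cm, sn, cn, T, **dw_kw) for (cn, sn) in labels]
        for (cm, sm) in labels
    ]

    def stacked(profile):
        return [profile[c][m] for c in classes for m in range(51)]

    total_w = sum(x[i] * areas[i] for i in range(nc))
    p_mix = [
        sum(x[i] * areas[i] * stacked(split_profiles[i])[k] for i in range(nc))
        / total_w
        for k in range(153)
    ]
    ln_gs = [math.log(g) for g in naive_segment_fixed_point(p_mix, dw, T, R)]
    out = []
    for i in range(nc):
        p_i = stacked(split_profiles[i])
        ln_gi = [math.log(g) for g in naive_segment_fixed_point(p_i, dw, T, R)]
        n_i = areas[i] / a_eff
        resid = n_i * sum(p_i[k] * (ln_gs[k] - ln_gi[k]) for k in range(153))
        out.append(comb[i] + resid)
    return out


def naive_flory_huggins(records, x, T, convention="per-volume", R=8.314):
    """records: list of (delta_d, delta_p, delta_h, V)."""
    nc = len(x)
    V = [rec[3] for rec in records]
    sv = sum(x[j] * V[j] for j in range(nc))
    phi = [x[j] * V[j] / sv for j in range(nc)]

    def dist(i, j):
        di, dj = records[i], records[j]
        return (
            (di[0] - dj[0]) ** 2
            + 0.25 * (di[1] - dj[1]) ** 2
            + 0.25 * (di[2] - dj[2]) ** 2
        )

    out = []
    for i in range(nc):
        comb = math.log(V[i] / sv) + 1.0 - V[i] / sv
        if convention == "regular":
            dbar = [
                sum(phi[j] * records[j][k] for j in range(nc)) for k in range(3)
            ]
            quad = (
                (records[i][0] - dbar[0]) ** 2
                + 0.25 * (records[i][1] - dbar[1]) ** 2
                + 0.25 * (records[i][2] - dbar[2]) ** 2
            )
            res = V[i] * quad / (R * T)
        else:
            if convention == "per-volume":
                chi = [[dist(j, k) / (R * T) for k in range(nc)] for j in range(nc)]
            else:
                chi = [
                    [V[j] * dist(j, k) / (R * T) for k in range(nc)]
                    for j in range(nc)
                ]
            res = 2.0 * V[i] * sum(
                chi[i][j] * phi[j] ** 2 for j in range(nc)
            ) - V[i] * sum(
                phi[j] * phi[k] * chi[j][k]
                for j in range(nc)
                for k in range(nc)
            )
        out.append(comb + res)
    return out


def naive_charge_average(sigmas, areas, positions, r_ave):
    """Term-by-term evaluation of the charge-averaging formula."""
    n = len(sigmas)
    out = []
    for m in range(n):
        num = den = 0.0
        for k in range(n):
            rn2 = areas[k] / math.pi
            pref = (r_ave**2 * rn2) / (r_ave**2 + rn2)
            d2 = sum((positions[m][d] - positions[k][d]) ** 2 for d in range(3))
            w = pref * math.exp(-d2 / (r_ave**2 + rn2))
            num += sigmas[k] * w
            den += w
        out.append(num / den)
    return out
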