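"""Event-driven core of the two-state branching simulator (numba-compiled).

Exact stochastic simulation of a population of cells in two states
(0 = drug-susceptible, 1 = primed). Each cell divides at its state's
division rate and dies at its state's death rate. State switching is
coupled to division by default: at every division each daughter
independently switches to the other state with the per-daughter
probability (``p_on`` for susceptible mothers, ``p_off`` for primed
mothers). The optional lineage-coupling coefficient ``gamma`` makes
susceptible cells in partially-primed lineages switch more easily:
``p_on_eff = p_on * (1 + gamma * lineage_primed_fraction)``.

A continuous-switching mode is available for sensitivity checks, in which
switching is a separate exponential event with per-cell rates ``k_on`` and
``k_off`` (no division needed).

Arrays are preallocated by the caller; the kernel returns a status code of
0 (reached ``t_end``), 1 (capacity overflow -- caller retries bigger) or
2 (population extinct).
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_OVERFLOW = 1
STATUS_EXTINCT = 2

# events array layout
EV_DIV_S, EV_DIV_P, EV_DEATH_S, EV_DEATH_P, EV_SW_ON, EV_SW_OFF = range(6)


@njit(cache=False)
def run_kernel(
    states,
    lineages,
    birth_times,
    lin_tot,
    lin_p,
    events,
    n0,
    t0,
    t_end,
    r_s,
    r_p,
    d_s,
    d_p,
    p_on,
    p_off,
    gamma,
    division_coupled,
    k_on,
    k_off,
    seed,
):
    np.random.seed(seed)
    cap = states.shape[0]
    n = n0
    n_p = 0
    for i in range(n):
        if states[i] == 1:
            n_p += 1
    n_s = n - n_p
    t = t0
    while n > 0:
        rate_div_s = n_s * r_s
        rate_div_p = n_p * r_p
        rate_death_s = n_s * d_s
        rate_death_p = n_p * d_p
        rate_sw_s = 0.0
        rate_sw_p = 0.0
        if not division_coupled:
            rate_sw_s = n_s * k_on
            rate_sw_p = n_p * k_off
        total = rate_div_s + rate_div_p + rate_death_s + rate_death_p + rate_sw_s + rate_sw_p
        if total <= 0.0:
            return n, t_end, STATUS_OK
        t += -np.log(np.random.random()) / total
        if t > t_end:
            return n, t_end, STATUS_OK
        u = np.random.random() * total
        if u < rate_div_s:
            ev = 0
            s = 0
        elif u < rate_div_s + rate_div_p:
            ev = 0
            s = 1
        elif u < rate_div_s + rate_div_p + rate_death_s:
            ev = 1
            s = 0
        elif u < rate_div_s + rate_div_p + rate_death_s + rate_death_p:
            ev = 1
            s = 1
        elif u < rate_div_s + rate_div_p + rate_death_s + rate_death_p + rate_sw_s:
            ev = 2
            s = 0
        else:
            ev = 2
            s = 1
        # pick a uniformly random cell of the required state
        idx = np.random.randint(n)
        while states[idx] != s:
            idx = np.random.randint(n)
        lin = lineages[idx]
        if ev == 0:  # division
            if n + 1 > cap:
                return n, t, STATUS_OVERFLOW
            events[EV_DIV_S + s] += 1
            dp = -1 if s == 1 else 0  # primed-count delta: mother removed
            for dtr in range(2):
                if s == 0:
                    p_eff = p_on
                    if gamma != 0.0 and lin_tot[lin] > 0:
                        p_eff = p_on * (1.0 + gamma * lin_p[lin] / lin_tot[lin])
                        if p_eff > 1.0:
                            p_eff = 1.0
                    switched = np.random.random() < p_eff
                else:
                    switched = np.random.random() < p_off
                d_state = 1 - s if switched else s
                if switched:
                    events[EV_SW_ON + s] += 1
                if d_state == 1:
                    dp += 1
                if dtr == 0:
                    states[idx] = d_state
                    birth_times[idx] = t
                else:
                    states[n] = d_state
                    lineages[n] = lin
                    birth_times[n] = t
            lin_tot[lin] += 1
            lin_p[lin] += dp
            n += 1
            n_p += dp
            n_s = n - n_p
        elif ev == 1:  # death
            events[EV_DEATH_S + s] += 1
            n -= 1
            states[idx] = states[n]
            lineages[idx] = lineages[n]
            birth_times[idx] = birth_times[n]
            lin_tot[lin] -= 1
            if s == 1:
                lin_p[lin] -= 1
                n_p -= 1
            else:
                n_s -= 1
            if n == 0:
                return n, t, STATUS_EXTINCT
        else:  # continuous-mode switch
            events[EV_SW_ON + s] += 1
            states[idx] = 1 - s
            if s == 0:
                n_p += 1
                n_s -= 1
                lin_p[lin] += 1
            else:
                n_p -= 1
                n_s += 1
                lin_p[lin] -= 1
    return n, t, STATUS_EXTINCT
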