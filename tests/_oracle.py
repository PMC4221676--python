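"""Independent brute-force oracle for the cohort state-transition engine.

Enumerates the *joint* disease-state distribution explicitly: the population
is a dict mapping (age_index, sex_index, pa_class, status_tuple) to an
expected count, where status_tuple holds one 0/1 flag per disease.  Every
transition (incidence per disease, death given the joint status, ageing, PA
drift) is applied by explicit enumeration over subsets of diseases, with no
shared code or vectorisation tricks from the engine under test.  Agreement
of the engine's marginal per-disease recursion with this joint enumeration
validates the independence/marginalisation algebra.
"""

from itertools import product

import numpy as np


def brute_force_run(demography, pa, diseases, n_cycles, shift=0.0,
                    other_cost_per_capita=0.0):
    """Replicates ChronicDiseaseModel.run outputs by joint-state enumeration.

    Conventions mirrored deliberately: incidence before mortality; deaths get
    a half person-year; utilities and prevalence use end-of-cycle states;
    ageing (top age absorbing) then PA drift close the cycle.  Returns a dict
    of per-cycle lists.
    """
    A = demography.n_ages
    K = pa.n_classes
    D = len(diseases)
    status0 = (0,) * D

    pop = {}
    occ = np.asarray(pa.occupancy, dtype=float)
    if occ.ndim == 1:
        occ = np.broadcast_to(occ, (A, 2, K))
    for a in range(A):
        for s in range(2):
            for k in range(K):
                count = demography.counts[a, s] * occ[a, s, k]
                if count > 0:
                    pop[(a, s, k, status0)] = count

    def onset_prob(d_idx, a, s, k):
        d = diseases[d_idx]
        if d.female_only and s == 0:
            return 0.0
        inc = np.asarray(d.incidence, dtype=float)
        base = float(inc) if inc.ndim == 0 else float(inc[a, s])
        met = max(float(pa.values[k]) + shift, 0.0)
        return base * float(np.exp(d.beta * (met - d.reference_met)))

    def excess(d_idx, a, s):
        e = np.asarray(diseases[d_idx].excess_mortality, dtype=float)
        return float(e) if e.ndim == 0 else float(e[a, s])

    out = {"life_years": [], "qalys": [], "deaths": [], "alive_end": [],
           "costs": [],
           "incidence": {d.name: [] for d in diseases},
           "prevalence": {d.name: [] for d in diseases}}

    for _ in range(n_cycles):
        # 1. incidence: enumerate which subset of free diseases is acquired
        new_pop = {}
        new_cases = np.zeros(D)
        for (a, s, k, st), count in pop.items():
            free = [i for i in range(D) if st[i] == 0]
            probs = {i: onset_prob(i, a, s, k) for i in free}
            for n_acq in range(len(free) + 1):
                from itertools import combinations
                for acquired in combinations(free, n_acq):
                    p = 1.0
                    for i in free:
                        p *= probs[i] if i in acquired else (1.0 - probs[i])
                    if p == 0.0:
                        continue
                    st2 = tuple(1 if (st[i] == 1 or i in acquired) else 0
                                for i in range(D))
                    key = (a, s, k, st2)
                    new_pop[key] = new_pop.get(key, 0.0) + count * p
                    for i in acquired:
                        new_cases[i] += count * p
        pop = new_pop

        # 2. mortality given the joint status
        survivors = {}
        deaths = 0.0
        person_years = 0.0
        qalys = 0.0
        prev_counts = np.zeros(D)
        costs = 0.0
        for (a, s, k, st), count in pop.items():
            surv = 1.0 - float(np.asarray(demography.mortality)[a, s])
            for i in range(D):
                if st[i]:
                    surv *= 1.0 - excess(i, a, s)
            alive = count * surv
            dead = count - alive
            deaths += dead
            py = count - 0.5 * dead
            person_years += py
            util = 1.0
            for i in range(D):
                if st[i]:
                    util *= 1.0 - diseases[i].disutility
            qalys += py * util
            for i in range(D):
                if st[i]:
                    prev_counts[i] += alive
                    c = np.asarray(diseases[i].annual_cost, dtype=float)
                    costs += alive * (float(c) if c.ndim == 0
                                      else float(c[a, s]))
            costs += py * other_cost_per_capita
            if alive > 0:
                survivors[(a, s, k, st)] = alive

        out["life_years"].append(person_years)
        out["qalys"].append(qalys)
        out["deaths"].append(deaths)
        out["alive_end"].append(sum(survivors.values()))
        out["costs"].append(costs)
        for i, d in enumerate(diseases):
            out["incidence"][d.name].append(new_cases[i])
            out["prevalence"][d.name].append(prev_counts[i])

        # 3. ageing (top age absorbing), then PA drift down one class
        aged = {}
        for (a, s, k, st), count in survivors.items():
            a2 = min(a + 1, A - 1)
            key = (a2, s, k, st)
            aged[key] = aged.get(key, 0.0) + count
        if pa.annual_drift > 0 and K > 1:
            drifted = {}
            for (a, s, k, st), count in aged.items():
                stay = count * (1.0 - pa.annual_drift)
                move = count * pa.annual_drift
                k2 = max(k - 1, 0)
                for kk, cc in ((k, stay), (k2, move)):
                    key = (a, s, kk, st)
                    drifted[key] = drifted.get(key, 0.0) + cc
            aged = drifted
        pop = aged

    return out


def engine_vs_oracle(model, n_cycles, shift=0.0):
    """Run the engine and the oracle on the same instance; return both."""
    schedule = (lambda t: shift) if shift else None
    traj = model.run(n_cycles, shift_schedule=schedule)
    oracle = brute_force_run(model.demography, model.pa, model.diseases,
                             n_cycles, shift=shift,
                             other_cost_per_capita=model.other_cost_per_capita)
    return traj, oracle
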