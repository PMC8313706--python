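"""Independent brute-force oracles, written in plain scalar Python.

These deliberately share no code with the package's vectorized engine: belief
updates, option values and softmax probabilities are spelled out trial by
trial with `math` arithmetic, so they can serve as an enumeration oracle for
the recursive likelihood.
"""

import math


def oracle_game_nll(
    trials,
    alpha,
    beta,
    k=0.0,
    nu=0.0,
    leak=None,
    gamma=None,
    model="nkRL",
    q0=50.0,
):
    """NLL of the free choices of ONE game, replayed with explicit arithmetic.

    ``trials`` is a list of (phase, choice, reward) tuples in trial order.
    """
    q = [q0, q0, q0]
    n_samples = [0, 0, 0]
    acc = [0.0, 0.0, 0.0]  # leaky accumulator
    seen = [False, False, False]
    nll = 0.0
    for phase, choice, reward in trials:
        if phase == "free":
            values = []
            for d in range(3):
                v = q[d]
                if model == "kRL":
                    v += n_samples[d] * k
                elif model == "nkRL":
                    v += n_samples[d] * k + (0.0 if seen[d] else nu)
                elif model == "leaky_nkRL":
                    v += acc[d] * k + (0.0 if seen[d] else nu)
                elif model == "gnkRL":
                    v += (n_samples[d] ** gamma) * k + (0.0 if seen[d] else nu)
                values.append(v)
            top = max(beta * v for v in values)
            exps = [math.exp(beta * v - top) for v in values]
            nll -= math.log(exps[choice] / sum(exps))
        if model == "leaky_nkRL":
            acc = [a * leak for a in acc]
        acc[choice] += 1.0
        n_samples[choice] += 1
        seen[choice] = True
        q[choice] = q[choice] + alpha * (reward - q[choice])
    return nll


def random_game_log(rng, subject_id="oracle"):
    """One random single-game trial log (rows as dicts), plus its trial list.

    Structure honors the task: 6 forced trials with (2,2,2) or (4,2,0)
    counts, then 1-6 free trials; rewards are arbitrary integers in 1..100.
    """
    unequal = bool(rng.random() < 0.5)
    if unequal:
        counts = [4, 2, 0]
        rng.shuffle(counts)
    else:
        counts = [2, 2, 2]
    forced = [d for d in range(3) for _ in range(counts[d])]
    rng.shuffle(forced)
    n_free = int(rng.integers(1, 7))
    frees = [int(rng.integers(0, 3)) for _ in range(n_free)]
    rows, trials = [], []
    for t, c in enumerate(forced + frees):
        phase = "forced" if t < 6 else "free"
        reward = int(rng.integers(1, 101))
        rows.append(
            {
                "subject_id": subject_id,
                "game_index": 0,
                "trial_index": t,
                "phase": phase,
                "info_condition": "UNEQUAL_INFO" if unequal else "EQUAL_INFO",
                "reward_condition": "EQUAL_REWARD",
                "choice": c,
                "reward": reward,
                "forced_deck": c if phase == "forced" else None,
            }
        )
        trials.append((phase, c, reward))
    return rows, trials
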