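import numpy as np
import pytest

from dialib import chem, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture(scope="session")
def small_proteome():
    return simulate.gen_proteome(n_proteins=10, seed=11)


def random_peptide(rng, min_len=6, max_len=20):
    n = int(rng.integers(min_len, max_len + 1))
    return "".join(rng.choice(simulate.RESIDUES, size=n, p=simulate.RESIDUE_PROBS))


def brute_force_digest(sequence, rule):
    """Independent digestion oracle: test the cleavage predicate at every
    bond, enumerate all missed-cleavage joins, filter lengths last."""
    cuts = [0]
    for i in range(len(sequence) - 1):
        if sequence[i] in rule.cut_after and (
            sequence[i + 1] not in rule.suppressors
        ):
            cuts.append(i + 1)
    cuts.append(len(sequence))
    frags = [(cuts[i], cuts[i + 1]) for i in range(len(cuts) - 1)]
    out = []
    for i in range(len(frags)):
        for m in range(rule.max_missed + 1):
            if i + m >= len(frags):
                break
            lo, hi = frags[i][0], frags[i + m][1]
            if rule.min_len <= hi - lo <= rule.max_len:
                out.append((sequence[lo:hi], lo + 1, hi, m))
    return out


def cumulative_fragment_oracle(seq, series, ordinal, charge, table=chem.DEFAULT_TABLE):
    """Independently coded cumulative-sum fragment m/z."""
    masses = [table.masses[aa] + table.fixed_modifications.get(aa, 0.0) for aa in seq]
    prefix = np.concatenate([[0.0], np.cumsum(masses)])
    if series == "b":
        neutral = prefix[ordinal]
    else:
        neutral = prefix[-1] - prefix[len(seq) - ordinal] + table.water
    return (neutral + charge * table.proton) / charge
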