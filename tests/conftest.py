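import numpy as np
import pytest

from clinabbr import AbbrevDictionary, EquivalenceTable


@pytest.fixture
def clinical_dict() -> AbbrevDictionary:
    """Hand-written sense inventory used across modules."""
    return AbbrevDictionary(
        [
            ("af", "atrial fibrillation"),
            ("af", "afebrile"),
            ("afib", "atrial fibrillation"),
            ("pt", "patient"),
            ("pt", "physical therapy"),
            ("pts", "patients"),
            ("cp", "chest pain"),
            ("hit", "heparin induced thrombocytopenia"),
            ("cb", "complicated by"),
            ("bl", "bilateral"),
            ("civ", "common iliac vein"),
            ("dvt", "deep venous thrombosis"),
            ("ccu", "cardiac care unit"),
            ("ccu", "coronary care unit"),
            ("us", "ultrasound"),
        ]
    )


@pytest.fixture
def ccu_equivalence() -> EquivalenceTable:
    return EquivalenceTable([("ccu", ["cardiac care unit", "coronary care unit"])])


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def enumerate_alignment_cost(a, b, scoring, dictionary=None):
    """Independent oracle: minimum alignment cost by exhaustive enumeration
    of all global alignments (every interleaving of diagonal / delete /
    insert moves), pricing insertion runs that directly follow an aligned
    abbreviation at the best applicable expansion-gap discount.

    Deliberately shares no code with the dynamic program it checks.
    """
    n, m = len(a), len(b)

    def licensed(token):
        if not scoring.enable_eg or dictionary is None or token not in dictionary:
            return ()
        return tuple(
            len(e.split()) - 1
            for e in dictionary.expansions_of(token)
            if len(e.split()) >= 2
        )

    def run_price(anchor_lens, runlen):
        price = runlen * scoring.indel
        for L in anchor_lens:
            if L <= runlen:
                gap = scoring.eg * L if scoring.eg_per_token else scoring.eg
                price = min(price, gap + (runlen - L) * scoring.indel)
        return price

    best = [float("inf")]

    def rec(i, j, cost, runlen, anchor):
        if cost >= best[0]:
            return
        if i == n and j == m:
            best[0] = min(best[0], cost + run_price(anchor, runlen))
            return
        if i < n and j < m:  # diagonal
            closed = cost + run_price(anchor, runlen)
            pair = (
                scoring.match
                if a[i] == b[j]
                else scoring.sfc
                if scoring.enable_sfc and a[i][:1] == b[j][:1]
                else scoring.mismatch
            )
            rec(i + 1, j + 1, closed + pair, 0, licensed(a[i]))
        if i < n:  # delete input token
            rec(i + 1, j, cost + run_price(anchor, runlen) + scoring.indel, 0, ())
        if j < m:  # insert output token (run stays open)
            rec(i, j + 1, cost, runlen + 1, anchor)

    rec(0, 0, 0.0, 0, ())
    return best[0]
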