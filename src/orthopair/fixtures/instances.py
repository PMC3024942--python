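"""Seeded random BLAST-table instances for the equivalence harness.

Instances are small (<= 5 organisms, <= 60 proteins) and deliberately messy:
E-values are drawn from a coarse exponent grid so that ties — including
E-value 0.0 ties resolved by bit score, and full (E-value, bit score) ties
resolved by accession — occur routinely, exercising every tie-break branch.
Every protein gets an explicit self-hit row, as a real all-versus-all search
would produce.
"""

from __future__ import annotations

import random

from ..blast_io import BlastHit


def random_instance(
    seed: int,
    max_organisms: int = 5,
    max_proteins: int = 60,
) -> tuple[dict[str, str], list[BlastHit]]:
    """One random instance: (accession -> organism map, hit rows)."""
    rng = random.Random(seed)
    n_org = rng.randint(2, max_organisms)
    organisms = [f"org{i}" for i in range(n_org)]
    acc_org: dict[str, str] = {}
    remaining = rng.randint(2 * n_org, max_proteins)
    for i, org in enumerate(organisms):
        left = len(organisms) - i - 1
        size = rng.randint(1, max(1, remaining - left))
        remaining -= size
        for j in range(size):
            acc_org[f"{org}p{j}"] = org

    exponents = [0, 5, 10, 20, 30, 40, 50, 80, 120, 180]
    bitscores = [50.0, 100.0, 200.0, 400.0, 800.0]
    hit_prob = rng.uniform(0.4, 0.9)
    hits: list[BlastHit] = []
    for q in sorted(acc_org):
        hits.append(BlastHit(q, q, 0.0, 5000.0, 100.0, 100))
        for s in sorted(acc_org):
            if s == q or rng.random() > hit_prob:
                continue
            exponent = rng.choice(exponents)
            evalue = 0.0 if exponent == 0 and rng.random() < 0.3 else 10.0 ** -max(exponent, 9)
            hits.append(
                BlastHit(
                    q,
                    s,
                    evalue,
                    rng.choice(bitscores),
                    round(rng.uniform(25.0, 95.0), 1),
                    rng.randint(50, 400),
                )
            )
    rng.shuffle(hits)
    return acc_org, hits
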