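"""Coordination networks against declared expectations.

Builds an expectations table from the planted co-regulation block (block
members are expected synergistic with a reference member, mimicking declared
pathway stimulators) plus deliberately false antagonism expectations on
independent genes, then scores each dataset's observed network against it.
Block expectations should match; the false ones should not.
"""

from pathlib import Path

import pandas as pd

from gfabric import (
    ExpressionTensor,
    compare_expected_relations,
    concordance_summary,
    coordination_network,
    read_expected_relations,
)

TENSORS = Path("results/tensors")
OUT = Path("results/coordination")
BLOCK = [f"g{i:05d}" for i in range(100, 140)]
TARGET = BLOCK[1]  # an ordinary block member (the low-CV hub's own edges are
                   # diluted by technical spot noise, so it is a poor anchor)
DECOYS = [f"g{i:05d}" for i in range(970, 980)]


def write_expectations(path: Path) -> None:
    rows = [("block_stim", m, TARGET, "+") for m in BLOCK[2:12]]
    rows += [("false_inhib", d, TARGET, "-") for d in DECOYS]
    pd.DataFrame(
        rows, columns=["group", "member_gene", "target_gene", "expected_sign"]
    ).to_csv(path, sep="\t", index=False)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    expectations_path = OUT / "expected_relations.tsv"
    write_expectations(expectations_path)
    relations = read_expected_relations(expectations_path)
    genes = sorted({r.member_gene for r in relations} | {r.target_gene for r in relations})
    for path in sorted(TENSORS.glob("tensor__*.tsv")):
        _, region, phenotype = path.stem.split("__")
        tensor = ExpressionTensor.read(path, region, phenotype)
        edges, _ = coordination_network(tensor, genes)
        table = compare_expected_relations(edges, relations)
        table.to_csv(OUT / f"concordance__{region}__{phenotype}.tsv", sep="\t", index=False)
        by_group = table.groupby("group")["match"].mean()
        counts = concordance_summary(table)
        print(
            f"{region}/{phenotype}: {counts['n_match']}/{counts['n_relations']} matched "
            f"(block_stim {100 * by_group.get('block_stim', 0):.0f}%, "
            f"false_inhib {100 * by_group.get('false_inhib', 0):.0f}%)"
        )


if __name__ == "__main__":
    main()
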