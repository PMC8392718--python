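"""Quality-control, normalize and assemble the simulated experiment.

Reads results/data/spots.tsv, removes corrupted and low-signal spots,
scales each array to median 1, assembles one expression tensor per
(region, phenotype) on the common gene universe, and reports what was
filtered.  Tensors land under results/tensors/.
"""

from pathlib import Path

from gfabric import ingest_spot_table, read_spot_table

IN = Path("results/data/spots.tsv")
OUT = Path("results/tensors")


def main() -> None:
    table = read_spot_table(IN)
    tensors, report = ingest_spot_table(table)
    OUT.mkdir(parents=True, exist_ok=True)
    report.write(OUT / "filter_report.json")
    for (region, phenotype), tensor in tensors.items():
        tensor.write(OUT / f"tensor__{region}__{phenotype}.tsv")
    n = report.n_genes_retained
    print(f"{report.n_input} rows in; removed {report.n_corrupted} corrupted, "
          f"{report.n_low_signal} low-signal, {report.n_nonpositive} non-positive")
    print(f"{len(tensors)} tensors with a common universe of N = {n} genes "
          f"({len(report.genes_dropped)} genes dropped)")


if __name__ == "__main__":
    main()
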