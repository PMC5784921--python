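"""Topology statistics table: one row per network, plus the published check.

Computes N, M, mean clustering, characteristic path length, Freeman degree
centralization, mean degree and density for the global network and each
focal subnetwork, and verifies the analytic identities (k = 2M/N,
ρ = 2M/(N(N−1)), Freeman centralization from N, M, k_max) against the
published topology table rows that are internally consistent.
"""

from pathlib import Path

import pandas as pd

from litmesh.network import import_graphml
from litmesh.topology import (
    centralization_from,
    density_from,
    mean_neighbors_from,
    reports_table,
    topology_report,
)

OUTDIR = Path(__file__).resolve().parent.parent / "results" / "analysis"

# Published rows used as analytic inputs: name -> (N, M) and, where the
# printed centralization is consistent with Freeman's formula, k_max.
PUBLISHED = {
    "Raw": (1229, 18451, None),
    "Global": (1037, 11830, 655),
    "SDH": (168, 1891, None),
    "HSD": (211, 2750, None),
    "HP": (104, 869, None),
    "WHO": (32, 197, 31),
    "GH": (140, 1525, 90),
}


def main() -> None:
    reports = [topology_report(import_graphml(OUTDIR / "global.graphml"), "global")]
    for path in sorted(OUTDIR.glob("subnet_*.graphml")):
        name = path.stem.removeprefix("subnet_").replace("_", " ")
        reports.append(topology_report(import_graphml(path), name))
    table = reports_table(reports)
    table.to_csv(OUTDIR / "topology_table.csv", index=False)
    print("synthetic-corpus topology table:")
    print(table.to_string(index=False))

    rows = []
    for name, (n, m, k_max) in PUBLISHED.items():
        rows.append(
            {
                "Network": name,
                "N": n,
                "M": m,
                "k=2M/N": round(mean_neighbors_from(n, m), 3),
                "rho=2M/(N(N-1))": round(density_from(n, m), 3),
                "Centralization": (
                    round(centralization_from(n, m, k_max), 3) if k_max else None
                ),
            }
        )
    published = pd.DataFrame(rows)
    published.to_csv(OUTDIR / "published_identities.csv", index=False)
    print("\nanalytic identities from the published node/edge counts:")
    print(published.to_string(index=False))
    print(
        "\n(centralization shown only for the rows whose printed value is "
        "consistent with Freeman's formula)"
    )


if __name__ == "__main__":
    main()
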