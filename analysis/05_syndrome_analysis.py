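#!/usr/bin/env python
"""Ask whether species-species links concentrate within trait syndromes.

Signed species-species links are classified by directed syndrome pair
(TT, QQ, TQ, QT; parent first) and tested with a chi-square goodness of
fit against two nulls: uniform class proportions and proportions implied
by the marginal syndrome frequencies.  Both are reported because the
appropriate null is a modelling choice.
"""

import json
from pathlib import Path

import pandas as pd

from vegnet.plot_data import read_plot_table, read_syndrome_map
from vegnet.signing import SignedLink
from vegnet.syndromes import (chi_square_gof, classify_links,
                              syndrome_null_proportions)

OUT = Path("results/analysis")


def main() -> None:
    table = read_plot_table(OUT / "plots.csv")
    syn = read_syndrome_map(OUT / "syndromes.csv")
    df = pd.read_csv(OUT / "signed_links.csv")
    links = [SignedLink(r.parent, r.child, r.strength, r.direction_support,
                        r.jt, r.z, r.p, r.sign) for r in df.itertuples()]

    report = {"counts_all": classify_links(links, syn, species=table.species),
              "counts_positive": classify_links(links, syn, species=table.species,
                                                positive_only=True)}
    obs = {k: report["counts_all"][k] for k in ("TT", "QQ", "TQ", "QT")}
    print("directed syndrome-pair counts:", obs,
          f"(same {report['counts_all']['same']}, "
          f"different {report['counts_all']['different']})")
    if sum(obs.values()):
        for mode in ("uniform", "frequency", "frequency_no_replacement"):
            res = chi_square_gof(obs, syndrome_null_proportions(syn, mode))
            report[f"chi2_{mode}"] = res.as_dict()
            print(f"  chi2 vs {mode} null: {res.chi2:.2f}, df {res.df}, p {res.p:.3g}")
    (OUT / "syndrome_analysis.json").write_text(json.dumps(report, indent=1,
                                                           sort_keys=True))


if __name__ == "__main__":
    main()
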