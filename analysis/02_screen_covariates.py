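"""Multicollinearity screen of the candidate covariates.

Computes variance inflation factors over the pooled panel (all
area-year rows) and iteratively drops covariates with VIF above 5;
writes the retained shortlist to results/study/vif.json.
"""

import json

import pandas as pd

import geotriad as gt
from common import RESULTS, study_panel


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    panel, _, _ = study_panel()
    table = pd.DataFrame(
        panel.covariates.reshape(-1, panel.n_covariates), columns=panel.covariate_names
    )
    retained, vifs, dropped = gt.vif_screen(table, threshold=5.0)
    (RESULTS / "vif.json").write_text(
        json.dumps({"retained": retained, "vif": vifs, "dropped": dropped}, indent=2)
    )
    for name, v in vifs.items():
        print(f"  VIF[{name}] = {v:.3f}")
    print(f"retained {len(retained)}/{panel.n_covariates} covariates "
          f"(dropped: {dropped or 'none'}); threshold 5")


if __name__ == "__main__":
    main()
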