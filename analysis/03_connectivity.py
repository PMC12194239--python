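#!/usr/bin/env python
"""Stage 3: connectivity and retention over the recruitment window.

Assigns each larva to the zone containing it at its first snapshot aged
110-120 days (115 +/- 5), tallies the 6x6 release x recruitment matrix,
and writes the matrix CSV, the density map, and a summary JSON.  Prints
the retention fraction and the top source and sink zones.
"""

from common import default_config
from urchindrift import pipeline


def main() -> None:
    cfg = default_config()
    summary = pipeline.cmd_connectivity(cfg)
    print(f"recruits in the 110-120 d window: {summary['total_recruits']} "
          f"of {summary['released']} released")
    if summary["total_recruits"]:
        print(f"retention (share of released recruited anywhere): "
              f"{summary['retention_fraction_pct']}%")
        print(f"top source zone: {summary['top_source']['zone']} "
              f"({summary['top_source']['pct']}% of recruits contributed)")
        print(f"top sink zone: {summary['top_sink']['zone']} "
              f"({summary['top_sink']['pct']}% of recruits received)")


if __name__ == "__main__":
    main()
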