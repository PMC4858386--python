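"""Analyte vocabulary for chlorination by-products.

Trihalomethanes (THMs) are volatile and absorbed by ingestion, inhalation
and dermal contact; haloacetic acids (HAAs) are non-volatile and taken up
essentially only by ingestion.  ``THMBr`` is the sum of the brominated
THMs, ``HAA3`` the sum of the three modelled HAAs, and ``DBP7`` the joint
THM+HAA metric (TTHM + DCAA + TCAA + BDCAA).
"""

from __future__ import annotations

#: individual trihalomethane species
THM_SPECIES = ("chloroform", "BDCM", "DBCM", "bromoform")

#: brominated THMs summed into THMBr
BROMINATED_THMS = ("BDCM", "DBCM", "bromoform")

#: THM analytes that concentration models may be fitted for.  Bromoform is
#: never modelled on its own (too heavily censored); it enters via THMBr.
THM_MODEL_ANALYTES = ("chloroform", "BDCM", "DBCM", "TTHM", "THMBr")

#: haloacetic acids with enough detectable data to model
HAA_ANALYTES = ("DCAA", "TCAA", "BDCAA")

#: THM analytes used in exposure metrics (uptake pathways)
THM_EXPOSURE_ANALYTES = ("chloroform", "BDCM", "DBCM", "THMBr", "TTHM")

ALL_MODEL_ANALYTES = THM_MODEL_ANALYTES + HAA_ANALYTES


def is_thm(analyte: str) -> bool:
    return analyte in THM_SPECIES or analyte in ("TTHM", "THMBr")


def is_haa(analyte: str) -> bool:
    return analyte in HAA_ANALYTES
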