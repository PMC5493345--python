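"""Sampling design of the central-Chile benthic fishery study.

Three management regimes — a no-take reserve (NT, Las Cruces), co-managed
territorial-use-rights areas (MA), and open access areas (OAA) — sampled at
three sites.  One comparative snapshot was taken in 2013 across all regimes;
MA stock assessments additionally provide annual samples from 1999 to 2013.
Per-cell sample sizes are the numbers of individuals measured (``None``
marks a year in which keyhole limpets were not recorded).

These rows parameterize the synthetic study fixture; no field data ship with
the package.
"""

from __future__ import annotations

LOCO = "loco"
LIMPET = "limpet"
SPECIES = (LOCO, LIMPET)

NT, MA, OAA = "NT", "MA", "OAA"
REGIMES = (NT, MA, OAA)

SNAPSHOT_YEAR = 2013

#: (site, year, regime, ma_id, n_fishing_grounds, n_loco, n_limpet)
STUDY_CELLS: list[tuple] = [
    ("Las Cruces", 2013, NT, None, 1, 282, 352),
    ("Las Cruces", 2013, OAA, None, 1, 136, 203),
    ("Algarrobo", 2013, OAA, None, 5, 422, 724),
    ("Algarrobo", 1999, MA, "A", None, 1062, 2266),
    ("Algarrobo", 2000, MA, "A", None, 972, 1127),
    ("Algarrobo", 2001, MA, "A", None, 595, 281),
    ("Algarrobo", 2002, MA, "A", None, 640, 843),
    ("Algarrobo", 2003, MA, "A", None, 210, 211),
    ("Algarrobo", 2004, MA, "A", None, 198, 158),
    ("Algarrobo", 2005, MA, "A", None, 143, 156),
    ("Algarrobo", 2006, MA, "A", None, 430, 879),
    ("Algarrobo", 2007, MA, "A", None, 995, 1044),
    ("Algarrobo", 2008, MA, "A", None, 248, 561),
    ("Algarrobo", 2009, MA, "A", None, 252, 196),
    ("Algarrobo", 2010, MA, "A", None, 225, 278),
    ("Algarrobo", 2013, MA, "A", 4, 220, 656),
    ("Algarrobo", 1999, MA, "B", None, 1531, 1556),
    ("Algarrobo", 2000, MA, "B", None, 991, 1590),
    ("Algarrobo", 2001, MA, "B", None, 560, 980),
    ("Algarrobo", 2002, MA, "B", None, 656, 1350),
    ("Algarrobo", 2003, MA, "B", None, 272, 715),
    ("Algarrobo", 2004, MA, "B", None, 325, 499),
    ("Algarrobo", 2005, MA, "B", None, 251, 390),
    ("Algarrobo", 2006, MA, "B", None, 635, 728),
    ("Algarrobo", 2007, MA, "B", None, 754, 1212),
    ("Algarrobo", 2011, MA, "B", None, 349, 363),
    ("Algarrobo", 2013, MA, "B", 5, 296, 424),
    ("Algarrobo", 1999, MA, "C", None, 1207, 1182),
    ("Algarrobo", 2000, MA, "C", None, 956, 1398),
    ("Algarrobo", 2001, MA, "C", None, 1075, 1294),
    ("Algarrobo", 2002, MA, "C", None, 1090, 1103),
    ("Algarrobo", 2003, MA, "C", None, 1289, 589),
    ("Algarrobo", 2004, MA, "C", None, 499, 467),
    ("Algarrobo", 2005, MA, "C", None, 209, 169),
    ("Algarrobo", 2006, MA, "C", None, 1077, 587),
    ("Algarrobo", 2007, MA, "C", None, 878, 467),
    ("Algarrobo", 2008, MA, "C", None, 520, 1010),
    ("Algarrobo", 2010, MA, "C", None, 175, 73),
    ("Algarrobo", 2011, MA, "C", None, 450, 449),
    ("Algarrobo", 2013, MA, "C", 3, 325, 498),
    ("Quintay", 2013, OAA, None, 13, 1352, 2699),
    ("Quintay", 2001, MA, "A", None, 6753, 6561),
    ("Quintay", 2002, MA, "A", None, 1920, 2614),
    ("Quintay", 2004, MA, "A", None, 443, 1040),
    ("Quintay", 2006, MA, "A", None, 595, 1052),
    ("Quintay", 2007, MA, "A", None, 1083, 1602),
    ("Quintay", 2011, MA, "A", None, 803, 1603),
    ("Quintay", 2013, MA, "A", 4, 208, 438),
    ("Quintay", 1999, MA, "B", None, 586, 1254),
    ("Quintay", 2000, MA, "B", None, 4906, 1775),
    ("Quintay", 2001, MA, "B", None, 2735, None),
    ("Quintay", 2002, MA, "B", None, 2506, 2486),
    ("Quintay", 2004, MA, "B", None, 508, 1042),
    ("Quintay", 2006, MA, "B", None, 446, 1593),
    ("Quintay", 2008, MA, "B", None, 1672, 756),
    ("Quintay", 2009, MA, "B", None, 478, 1378),
    ("Quintay", 2011, MA, "B", None, 1039, 1586),
    ("Quintay", 2013, MA, "B", 7, 462, 718),
]


def sample_size(cell: tuple, species: str) -> int | None:
    """Measured sample size of ``species`` in a STUDY_CELLS row."""
    if species == LOCO:
        return cell[5]
    if species == LIMPET:
        return cell[6]
    raise ValueError(f"unknown species {species!r}")
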