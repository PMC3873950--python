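# The rootarch MTG dialect

Digitized root systems are traditionally coded as multiscale tree graphs
(MTG): a text format carrying plant topology plus per-entity features.
The full MTG grammar supports arbitrary scale hierarchies and feature
sets; digitized coarse-root data only ever uses a flat two-scale corner
of it (axes and segments with coordinates, a diameter and fine-root
counts).  `rootarch` reads and writes exactly that corner and rejects
anything else with an explicit error.

## Grammar

```
MTG-DIALECT v1
UNIT: mm                 # mm | cm | m; applies to all lengths in the file
COLLAR: 0 0 0            # collar position (same unit)
PLANT: p1                # optional metadata ------------------------------
SLOPE_DEG: 45
FLEXED: True
BLOCK: B1
CONTAINER: 0.3 0.3 0.11  # always metres: width x, width y, soil depth
SHOOT_DW_G: 25.3
ROOT_DW_G: 8.1           # ----------------------------------------------
FEATURES: XX YY ZZ Diameter FineRootN FineRootLen
DATA:
S1  -     0 0 -50    5.0  0 0
S2  <S1   0 0 -100   4.0  0 0
S3  +S1   40 0 -50   1.2  2 15
```

* One row per root segment: `<id> <topology> XX YY ZZ Diameter FineRootN
  FineRootLen`, whitespace-separated.  `XX YY ZZ` is the segment **tip**;
  the base is the parent's tip (the collar row takes its base from
  `COLLAR:`).
* Topology codes: `-` the collar segment (exactly one), `<P` successor of
  segment `P` on the same axis (same root order), `+P` a lateral branch
  borne by segment `P` (new axis, order + 1).
* `Diameter` is the basal diameter of the segment; `FineRootN` /
  `FineRootLen` are the count and mean length of the unmeasured
  "additional fine roots" (basal diameter < 0.7 mm) borne by the segment.
* Row order is irrelevant: parents may be declared after their children.
  Axis identifiers are assigned deterministically by a depth-first
  traversal with children sorted by segment id.

Frame convention: X = north = upslope (azimuth 0 deg), Y parallel to the
upper container border, Z perpendicular to the soil surface and positive
upward (depths negative), collar at the origin.

## Errors

* malformed header or row -> `MTGFormatError` naming the line;
* unknown parent id -> `StructureError` listing the orphan ids;
* duplicate collar rows, cycles, unreachable segments -> `StructureError`;
* negative diameter -> `ValidationError`.

## Portable segment table

`write_segment_table` / `read_segment_table` provide the same content as
a flat CSV (units: metres) with the metadata in `#`-prefixed header
lines — convenient for spreadsheets and R.  Both formats round-trip to
1e-6 m.
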