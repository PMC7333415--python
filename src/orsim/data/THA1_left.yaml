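id: THA1
procedure: THA
side: left
room:
  width: 6.5
  height: 6.5
obstacles:
- id: rack_r1
  rect:
  - 1.2
  - 6.3
  - 1.8
  - 6.5
- id: rack_r2
  rect:
  - 4.3
  - 6.3
  - 4.9
  - 6.5
- id: anesthesia_station
  rect:
  - 5.9
  - 4.0
  - 6.5
  - 5.0
- id: solution_stand
  rect:
  - 0.0
  - 1.9
  - 0.35
  - 2.4
destinations:
  R1:
  - 1.5
  - 5.85
  R2:
  - 4.6
  - 5.85
  AR:
  - 6.25
  - 3.0
  sterile_room_door:
  - 0.25
  - 3.0
  ST1:
  - 0.25
  - 2.8
  ST2:
  - 0.35
  - 3.6
  WP1:
  - 0.75
  - 0.9
  WP2:
  - 0.75
  - 4.6
furniture:
- id: or_table
  kind: or_table
  center:
  - 3.9
  - 3.0
  footprint:
  - 2.0
  - 0.9
- id: table1
  kind: instrument_table
  center:
  - 3.2
  - 3.9
  footprint:
  - 0.6
  - 0.4
  table_angle: 0.0
- id: table2
  kind: instrument_table
  center:
  - 2.3
  - 4.7
  footprint:
  - 0.6
  - 0.4
  table_angle: 270.0
- id: table3
  kind: instrument_table
  center:
  - 1.55
  - 4.45
  footprint:
  - 0.6
  - 0.4
  table_angle: 215.0
- id: table4
  kind: instrument_table
  center:
  - 1.45
  - 3.9
  footprint:
  - 0.6
  - 0.4
  table_angle: 180.0
agents:
- role: SN
  position:
  - 2.3
  - 3.9
  facing:
  - 1.0
  - 0.0
- role: SU
  position:
  - 3.9
  - 3.75
  facing:
  - 0.13216372009101807
  - -0.9912279006826347
- role: A1
  position:
  - 4.6
  - 3.75
  facing:
  - -0.6246950475544241
  - -0.7808688094430306
- role: A2
  position:
  - 3.9
  - 2.25
  facing:
  - 0.13216372009101807
  - 0.9912279006826347
- role: AN
  position:
  - 5.3
  - 3.9
  facing:
  - -1.0
  - 0.0
- role: CIRC
  position:
  - 0.75
  - 0.9
  facing:
  - 1.0
  - 0.0
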