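trial_id,series,site_id,genotype_id,is_check,replicate,sub_block,yield_t_ha
T10L,10,10L,CHK1,True,1,1,2.25
T10L,10,10L,CHK2,True,1,1,2.15
T10L,10,10L,A1,False,1,1,2.5
T10L,10,10L,A2,False,1,1,2.4
T10L,10,10L,A3,False,1,2,2.3
T10L,10,10L,A4,False,1,2,2.2
T10L,10,10L,A5,False,1,2,2.1
T10L,10,10L,A6,False,1,2,2.0
T10L,10,10L,CHK1,True,2,1,2.25
T10L,10,10L,CHK2,True,2,1,2.15
T10L,10,10L,A1,False,2,1,2.5
T10L,10,10L,A2,False,2,1,2.4
T10L,10,10L,A3,False,2,2,2.3
T10L,10,10L,A4,False,2,2,2.2
T10L,10,10L,A5,False,2,2,2.1
T10L,10,10L,A6,False,2,2,2.0
T10M,10,10M,CHK1,True,1,1,4.45
T10M,10,10M,CHK2,True,1,1,4.35
T10M,10,10M,A1,False,1,1,4.7
T10M,10,10M,A2,False,1,1,4.6
T10M,10,10M,A3,False,1,2,4.5
T10M,10,10M,A4,False,1,2,4.4
T10M,10,10M,A5,False,1,2,4.3
T10M,10,10M,A6,False,1,2,4.2
T10M,10,10M,CHK1,True,2,1,4.45
T10M,10,10M,CHK2,True,2,1,4.35
T10M,10,10M,A1,False,2,1,4.7
T10M,10,10M,A2,False,2,1,4.6
T10M,10,10M,A3,False,2,2,4.5
T10M,10,10M,A4,False,2,2,4.4
T10M,10,10M,A5,False,2,2,4.3
T10M,10,10M,A6,False,2,2,4.2
T10H,10,10H,CHK1,True,1,1,6.65
T10H,10,10H,CHK2,True,1,1,6.55
T10H,10,10H,A1,False,1,1,6.9
T10H,10,10H,A2,False,1,1,6.8
T10H,10,10H,A3,False,1,2,6.7
T10H,10,10H,A4,False,1,2,6.6
T10H,10,10H,A5,False,1,2,6.5
T10H,10,10H,A6,False,1,2,6.4
T10H,10,10H,CHK1,True,2,1,6.65
T10H,10,10H,CHK2,True,2,1,6.55
T10H,10,10H,A1,False,2,1,6.9
T10H,10,10H,A2,False,2,1,6.8
T10H,10,10H,A3,False,2,2,6.7
T10H,10,10H,A4,False,2,2,6.6
T10H,10,10H,A5,False,2,2,6.5
T10H,10,10H,A6,False,2,2,6.4
T11L,11,11L,CHK1,True,1,1,2.35
T11L,11,11L,CHK2,True,1,1,2.25
T11L,11,11L,B1,False,1,1,2.75
T11L,11,11L,B2,False,1,1,2.55
T11L,11,11L,B3,False,1,2,2.42
T11L,11,11L,B4,False,1,2,2.32
T11L,11,11L,B5,False,1,2,2.22
T11L,11,11L,B6,False,1,2,2.12
T11L,11,11L,CHK1,True,2,1,2.35
T11L,11,11L,CHK2,True,2,1,2.25
T11L,11,11L,B1,False,2,1,2.75
T11L,11,11L,B2,False,2,1,2.55
T11L,11,11L,B3,False,2,2,2.42
T11L,11,11L,B4,False,2,2,2.32
T11L,11,11L,B5,False,2,2,2.22
T11L,11,11L,B6,False,2,2,2.12
T11M,11,11M,CHK1,True,1,1,4.55
T11M,11,11M,CHK2,True,1,1,4.45
T11M,11,11M,B1,False,1,1,4.95
T11M,11,11M,B2,False,1,1,4.75
T11M,11,11M,B3,False,1,2,4.62
T11M,11,11M,B4,False,1,2,4.52
T11M,11,11M,B5,False,1,2,4.42
T11M,11,11M,B6,False,1,2,4.32
T11M,11,11M,CHK1,True,2,1,4.55
T11M,11,11M,CHK2,True,2,1,4.45
T11M,11,11M,B1,False,2,1,4.95
T11M,11,11M,B2,False,2,1,4.75
T11M,11,11M,B3,False,2,2,4.62
T11M,11,11M,B4,False,2,2,4.52
T11M,11,11M,B5,False,2,2,4.42
T11M,11,11M,B6,False,2,2,4.32
T11H,11,11H,CHK1,True,1,1,6.75
T11H,11,11H,CHK2,True,1,1,6.65
T11H,11,11H,B1,False,1,1,7.15
T11H,11,11H,B2,False,1,1,6.95
T11H,11,11H,B3,False,1,2,6.82
T11H,11,11H,B4,False,1,2,6.72
T11H,11,11H,B5,False,1,2,6.62
T11H,11,11H,B6,False,1,2,6.52
T11H,11,11H,CHK1,True,2,1,6.75
T11H,11,11H,CHK2,True,2,1,6.65
T11H,11,11H,B1,False,2,1,7.15
T11H,11,11H,B2,False,2,1,6.95
T11H,11,11H,B3,False,2,2,6.82
T11H,11,11H,B4,False,2,2,6.72
T11H,11,11H,B5,False,2,2,6.62
T11H,11,11H,B6,False,2,2,6.52
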