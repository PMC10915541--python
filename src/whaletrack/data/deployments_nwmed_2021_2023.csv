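animal_id,tag_type,first_uplink,last_uplink,n_raw_locations
212759,MK10,2021-05-08,2021-05-22,302
212761,SPOT6,2021-05-06,2021-06-06,473
212762,SPOT6,2021-05-07,2021-05-31,717
232681,SPOT6,2022-05-12,2022-05-21,209
232682,SPOT6,2022-05-12,2022-06-07,546
232683,SPOT6,2022-05-14,2022-06-08,449
232684,SPOT6,2022-05-15,2022-06-07,412
232685,SPOT6,2022-05-15,2022-05-23,109
232686,SPOT6,2023-06-04,2023-07-22,1078
232687,SPOT6,2023-06-05,2023-06-21,328
232688,SPOT6,2023-06-05,2023-07-10,764
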