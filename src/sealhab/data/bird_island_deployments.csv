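year,animal_id,n_locations,start_date,end_date,duration_days
1999,W5727_9377,282,01/05/1999,06/07/1999,66
1999,W5757_6074,415,01/05/1999,22/06/1999,52
1999,W5767_9375,181,01/05/1999,18/06/1999,48
1999,W5773_9374,158,02/05/1999,22/05/1999,20
1999,W5793_6076,78,01/05/1999,04/08/1999,95
1999,W5797_6072,95,01/05/1999,19/06/1999,49
1999,W5801_9373,97,01/05/1999,13/05/1999,12
1999,W5811_9301,169,01/05/1999,22/05/1999,21
2003,W6478_1527,143,28/05/2003,15/06/2003,18
2003,W6479_30205,913,01/05/2003,30/09/2003,152
2003,W6876_30204,99,19/05/2003,26/09/2003,130
2003,W6879_30206,1023,06/05/2003,12/09/2003,129
2003,W6880_30203,254,08/05/2003,30/09/2003,145
2003,W6881_30201,480,01/05/2003,31/08/2003,122
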