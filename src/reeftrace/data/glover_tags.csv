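shark_id,transmitter_id,tag_type,battery_days,attachment,tag_date,sex,total_length_cm,maturity,tagging_site_label,tag_lat,tag_lon,n_days_detected,duration_days,mld_km,ri
18,18,V9,365,internal,2007-05-03,F,110,juvenile,MC,16.73,-87.8,259,359,17.92,0.71
19,19,V9,365,internal,2007-05-09,F,119,juvenile,MC,16.73,-87.8,361,356,5.44,0.99
20,20,V9,365,internal,2007-05-01,M,96,juvenile,EL,16.78,-87.76,111,362,5.44,0.30
21,21,V9,365,internal,2007-05-02,M,119,juvenile,EL,16.78,-87.76,320,360,17.92,0.88
22,22,V9,365,internal,2007-05-03,F,66,juvenile,MC,16.73,-87.8,84,229,13.74,0.23
23,23,V9,365,internal,2007-05-16,F,91,juvenile,EL,16.78,-87.76,270,348,5.44,0.74
223,223,V9,365,internal,2007-05-03,F,90,juvenile,MC,16.73,-87.8,229,359,17.92,0.63
234,234,V9,365,internal,2006-05-09,F,80,juvenile,SE,16.7,-87.84,348,355,9.15,0.95
235,235,V9,365,internal,2006-05-25,F,90,juvenile,EL,16.78,-87.76,204,321,1.25,0.56
236,236,V9,365,internal,2006-05-12,M,135,juvenile,SE,16.7,-87.84,134,426,17.92,0.37
237,237,V9,365,internal,2006-05-25,F,85,juvenile,MC,16.73,-87.8,43,468,4.33,0.12
238,238,V9,365,internal,2006-05-03,M,101,juvenile,SE,16.7,-87.84,198,362,8.44,0.54
239,239,V9,365,internal,2006-05-06,M,86,juvenile,EL,16.78,-87.76,161,475,1.25,0.44
240,240,V9,365,internal,2006-05-01,F,120,juvenile,SE,16.7,-87.84,17,147,5.8,0.05
3291,3291,V16,540,external,2006-05-01,F,214,adult,LAG,16.76,-87.82,24,87,5.56,0.04
3292,3292,V16,540,external,2006-10-10,F,214,adult,EL,16.78,-87.76,215,220,11.56,0.39
3346,3346,V16,540,internal,2006-08-15,F,135,juvenile,SE,16.7,-87.84,86,274,24.21,0.16
3348,3348,V16,540,internal,2004-05-05,M,188,adult,MC,16.73,-87.8,386,484,36.46,0.71
3349,3349,V16,540,internal,2004-05-12,F,134,juvenile,SE,16.7,-87.84,76,327,36.36,0.14
3372,3372,V16,540,internal,2006-05-12,F,136,juvenile,SE,16.7,-87.84,69,358,7.61,0.13
3373,3373,V16,540,internal,2005-07-02,F,110,juvenile,SE,16.7,-87.84,170,424,36.46,0.31
3374,3374,V16,540,internal,2005-05-28,F,142,juvenile,SE,16.7,-87.84,50,175,3.14,0.09
3376,3376,V16,540,internal,2006-10-13,F,176,juvenile,SE,16.7,-87.84,146,303,8.53,0.27
3378,3378,V16,540,internal,2007-05-11,F,156,juvenile,NLAG,16.82,-87.8,17,65,26.59,0.05
3379,3379,V16,540,internal,2006-05-09,M,166,adult,SE,16.7,-87.84,136,466,13.11,0.25
3383,3383,V16,540,internal,2005-05-31,F,124,juvenile,SE,16.7,-87.84,143,510,36.46,0.26
3391,3391,V16,540,internal,2005-05-24,M,167,adult,EL,16.78,-87.76,534,585,20.81,0.98
3340,3340,V16,540,internal,2004-05-06,M,197,adult,SE,16.7,-87.84,403,534,28.5,0.74
3393,3393,V16,540,internal,2004-05-06,M,117,juvenile,SE,16.7,-87.84,458,506,28.5,0.84
4603,4603,V16,540,internal,2007-12-18,M,176,adult,MC,16.73,-87.8,47,134,4.66,0.31
4604,4604,V16,540,internal,2007-05-21,F,122,juvenile,WLAG,16.75,-87.86,5,44,1.25,0.01
4607,4607,V16,540,internal,2007-05-07,M,151,juvenile,MC,16.73,-87.8,189,184,23.92,0.52
4608,4608,V16,540,internal,2007-05-07,M,183,adult,SE,16.7,-87.84,236,359,13.58,0.65
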